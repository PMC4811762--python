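#!/usr/bin/env python
"""Simulate a demonstration cohort and write it to disk.

Generates a small Stroop/Reading cohort (4 subjects, 12 frontal
electrodes plus reference-only contacts) with the default planted
effects — 215 ms congruency delay, Gratton RT structure, conflict-locked
high-gamma with the ACC-led latency cascade — and writes HDF5 recordings,
TSV trial tables and per-trial WAV audio under results/demo/sim/.

The later scripts (02-07) re-derive every reported quantity from these
synthetic data or from equivalently seeded in-memory cohorts.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from conflictlfp import io, synth  # noqa: E402

OUT = Path(__file__).resolve().parents[1] / "results" / "demo" / "sim"

CONFIG = synth.SimConfig(
    n_subjects=4, n_blocks_stroop=10, n_blocks_reading=5,
    electrodes_per_region={"ACC": 4, "dlPFC": 4, "mFC": 4},
    seed=2016)


def main() -> None:
    plan = synth.make_channel_plan(CONFIG)
    _, _, audio_ss = synth._seed_streams(CONFIG)
    audio_rngs = audio_ss.spawn(CONFIG.n_subjects)
    for s in range(CONFIG.n_subjects):
        trials, rec = synth.simulate_subject(CONFIG, s, plan=plan)
        io.write_trials(OUT / f"subject_{s:02d}_trials.tsv", trials)
        io.write_recording(OUT / f"subject_{s:02d}.h5", rec)
        if s == 0:  # audio for one subject is enough for the demo
            traces = synth.synthesize_audio(
                trials.head(40), rng=np.random.default_rng(audio_rngs[s]))
            io.write_audio(OUT / "audio_subject_00", trials.head(40),
                           traces)
        n_i = (trials["congruency"] == "I").mean()
        print(f"subject {s}: {len(trials)} trials "
              f"({n_i:.0%} incongruent), {rec.n_channels} channels "
              f"({(~rec.channels['aux']).sum()} analysed)")
    print(f"wrote cohort to {OUT}")


if __name__ == "__main__":
    main()
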