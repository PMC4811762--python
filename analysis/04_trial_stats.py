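#!/usr/bin/env python
"""Single-electrode statistics on the conflict-selective electrodes.

For each selective electrode of a small effect cohort: the power-RT
correlation on incongruent trials, the raw and RT-controlled (ANCOVA
and histogram-matched) Gratton contrasts.  Writes
results/demo/trial_stats.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from conflictlfp import selectivity, synth, trial_stats, workflows  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "demo"

CONFIG = synth.SimConfig(
    n_subjects=3, electrodes_per_region={"ACC": 3, "dlPFC": 3},
    seed=2017)


def main() -> None:
    rng = np.random.default_rng(11)
    rows = []
    for s, tri, ts, tr, lab in workflows.cohort_tensors(CONFIG):
        rts = tri["rt"].to_numpy()[tr.trial_index]
        hist = tri["history"].to_numpy()[tr.trial_index]
        rep = tri["stim_repeat"].to_numpy()[tr.trial_index]
        for e in range(tr.n_electrodes):
            res = selectivity.select_electrode(tr, lab[1], e, 0.001,
                                               1000, rng)
            if not res.selective:
                continue
            sc = trial_stats.single_trial_power(tr, e, "max")
            r, p = trial_stats.power_rt_correlation(
                sc.values[lab[1]], rts[lab[1]], 1000, rng)
            keep = ~rep
            raw = trial_stats.gratton_contrast(sc.values[keep], hist[keep])
            try:
                anc, anc_p = trial_stats.gratton_ancova(
                    sc.values[keep], hist[keep], rts[keep])
                mat, ret, _ = trial_stats.rt_matched_subsample(
                    sc.values[keep], hist[keep], rts[keep], rng=rng)
            except trial_stats.TrialStatsError:
                anc = anc_p = mat = ret = np.nan
            rows.append(dict(subject=s, electrode=e, power_rt_r=r,
                             power_rt_p=p, gratton_raw=raw,
                             gratton_ancova=anc, gratton_ancova_p=anc_p,
                             gratton_matched=mat, retention=ret))
    df = pd.DataFrame(rows)
    OUT.mkdir(parents=True, exist_ok=True)
    df.to_csv(OUT / "trial_stats.tsv", sep="\t", index=False)
    print(f"{len(df)} selective electrodes analysed")
    print(f"power-RT correlation: mean r = {df['power_rt_r'].mean():.2f} "
          f"({(df['power_rt_r'] > 0).sum()}/{len(df)} positive)")
    print(f"Gratton contrast (raw / ANCOVA / matched): "
          f"{df['gratton_raw'].mean():.1f} / "
          f"{df['gratton_ancova'].mean():.1f} / "
          f"{df['gratton_matched'].mean():.1f} power units; "
          f"matching retained {df['retention'].mean():.0%} of trials")
    print("(this cohort plants history structure in the RTs only, so "
          "the RT-controlled contrasts are expected to sit at zero)")
    print(f"wrote {OUT / 'trial_stats.tsv'}")


if __name__ == "__main__":
    main()
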