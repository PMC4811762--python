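#!/usr/bin/env python
"""Population-level inference with electrodes nested in subjects.

Fits the multilevel (mixed) model of single-trial gamma power with a
Congruency x Task interaction on a two-task cohort, tests it with a
likelihood-ratio test, and reports the population sign-rank test of the
per-electrode power-RT correlations.  Writes
results/demo/group_stats.json.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from conflictlfp import group_stats, io, synth, trial_stats, \
    workflows  # noqa: E402

ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results" / "demo"

CONFIG = synth.SimConfig(
    n_subjects=4, electrodes_per_region={"ACC": 4, "dlPFC": 4},
    seed=2018)


def main() -> None:
    recs, r_vals = [], []
    for task in ("Stroop", "Reading"):
        for s, tri, ts, tr, lab in workflows.cohort_tensors(CONFIG,
                                                            task=task):
            rts = tri["rt"].to_numpy()[tr.trial_index]
            for e in range(tr.n_electrodes):
                sc = trial_stats.single_trial_power(tr, e, "max")
                recs.append(pd.DataFrame(dict(
                    power=sc.values, congruency=lab[1].astype(int),
                    task=int(task == "Stroop"), subject=s,
                    electrode=f"s{s}e{e}")))
                if task == "Stroop":
                    r_vals.append(np.corrcoef(sc.values[lab[1]],
                                              rts[lab[1]])[0, 1])
    dat = pd.concat(recs, ignore_index=True)
    res = group_stats.multilevel_test(dat, "power", "congruency * task",
                                      "congruency + task",
                                      "congruency:task")
    print(f"Congruency x Task interaction: chi2 = {res.chi2:.1f}, "
          f"df = {res.df}, p = {res.p:.2g}"
          + (f" [{res.fallback}]" if res.fallback else ""))
    p_sr = group_stats.population_signrank(np.asarray(r_vals), "greater")
    print(f"power-RT correlations across {len(r_vals)} electrodes: "
          f"median r = {np.median(r_vals):.2f}, sign-rank p = {p_sr:.2g}")
    io.write_json(OUT / "group_stats.json",
                  dict(chi2=res.chi2, df=res.df, p=res.p,
                       signrank_p=p_sr, n_electrodes=len(r_vals)))
    print(f"wrote {OUT / 'group_stats.json'}")


if __name__ == "__main__":
    main()
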