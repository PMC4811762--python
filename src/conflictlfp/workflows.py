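"""Population-scale procedures composed from the module primitives.

These are the entry points the numbered analysis scripts and the
acceptance re-computation share: building a cohort's power tensors,
running the selection procedure over every electrode, and the null
false-positive calibration of the full detection cascade.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from . import selectivity
from .preprocess import epoch_band_power, notch_and_rereference, \
    subset_channels
from .synth import SimConfig, make_channel_plan, simulate_subject

log = logging.getLogger("conflictlfp")

STIM_WINDOW = (-0.5, 1.5)
RESP_WINDOW = (-1.5, 0.5)


def null_config(seed: int, electrodes_per_region: dict | None = None,
                n_subjects: int = 15) -> SimConfig:
    """Cohort with task-responsive electrodes but no conflict effect.

    Every effect coupling is off (power ratio 1, no RT-gain coupling, no
    trial-level gain jitter, no theta/beta suppression), so the
    across-bin correlation of the power traces comes from the 200 ms /
    10 ms multitaper windowing alone while the amplitude criterion still
    passes.
    """
    kw = {}
    if electrodes_per_region is not None:
        kw["electrodes_per_region"] = electrodes_per_region
    return SimConfig(n_subjects=n_subjects, gamma_effect_size=1.0,
                     power_rt_coupling=0.0, gain_jitter_sd=0.0,
                     theta_beta_suppression=0.0, seed=seed, **kw)


def cohort_tensors(config: SimConfig, band: str = "high-gamma",
                   task: str = "Stroop",
                   stim_window=STIM_WINDOW, resp_window=RESP_WINDOW):
    """Simulate + preprocess every subject; return per-subject tensors.

    Yields ``(subject, trials, tensor_stim, tensor_resp, labels)`` with
    ``labels`` the incongruent mask per alignment (correct trials only).
    """
    plan = make_channel_plan(config)
    for s in range(config.n_subjects):
        trials, rec = simulate_subject(config, s, task=task, plan=plan)
        rec = notch_and_rereference(rec)
        if "aux" in rec.channels:
            rec = subset_channels(rec, ~rec.channels["aux"].to_numpy(bool))
        ok = trials["correct"] & trials["rt"].notna()
        tri = trials[ok].reset_index(drop=True)
        ts = epoch_band_power(rec, tri, band, "stimulus", stim_window)
        tr = epoch_band_power(rec, tri, band, "response", resp_window)
        lab = (tri["congruency"] == "I").to_numpy()
        yield s, tri, ts, tr, (lab[ts.trial_index], lab[tr.trial_index])


def null_selection_fp(config: SimConfig, n_shuffles: int = 100,
                      alpha: float = 0.001, n_perm: int = 1000,
                      seed: int = 0, reuse_thresholds: bool = True):
    """False-positive calibration of the full selection procedure.

    Builds the null cohort, shuffles congruent/incongruent labels per
    electrode ``n_shuffles`` times, re-runs the complete selection
    (per-bin permutation threshold at ``alpha``, 50 ms run rule,
    amplitude criterion, both alignments) and returns
    ``dict(mean=..., sem=..., q=..., n_electrodes=...)``.
    """
    pairs, labels = [], []
    for s, _, ts, tr, lab in cohort_tensors(config):
        pairs.append((ts, tr))
        labels.append(list(lab))
        log.info("null cohort subject %d ready (%d electrodes)", s,
                 ts.n_electrodes)
    mean, sem, q, fired = selectivity.estimate_false_positives(
        pairs, labels, n_shuffles=n_shuffles, alpha=alpha, n_perm=n_perm,
        rng=seed, reuse_thresholds=reuse_thresholds)
    return dict(mean=mean, sem=sem, q=q, n_electrodes=fired.shape[0],
                n_shuffles=n_shuffles, n_perm=n_perm, alpha=alpha)


def select_population(config: SimConfig, alpha: float = 0.001,
                      n_perm: int = 1000, seed: int = 0,
                      n_boot: int = 0) -> pd.DataFrame:
    """Run response-aligned selection over every electrode of a cohort.

    Returns one row per electrode with region/subject metadata, the
    selective flag, detection latency and (when ``n_boot`` > 0 and the
    electrode qualifies) its bootstrap mean and s.e.m.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    plan = make_channel_plan(config)
    plan = plan[~plan["aux"]]
    rows = []
    for s, tri, ts, tr, lab in cohort_tensors(config):
        chans = plan[plan["subject"] == s].reset_index(drop=True)
        for e in range(tr.n_electrodes):
            res = selectivity.select_electrode(tr, lab[1], e, alpha,
                                               n_perm, rng)
            row = dict(subject=s, electrode=int(chans.loc[e, "channel"]),
                       region=chans.loc[e, "region"],
                       selective=res.selective,
                       amplitude_ok=res.amplitude_ok,
                       latency=res.latency,
                       pre_response=res.pre_response,
                       latency_mean=np.nan, latency_sem=np.nan)
            if n_boot and res.selective and res.pre_response:
                m, sem, lost = selectivity.latency_bootstrap(
                    tr, lab[1], res.threshold, e, n_boot, rng)
                row.update(latency_mean=m, latency_sem=sem,
                           boot_lost=lost)
            rows.append(row)
    return pd.DataFrame(rows)
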