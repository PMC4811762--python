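"""Shared fixtures: small synthetic cohorts generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from conflictlfp import synth
from conflictlfp.preprocess import epoch_band_power, notch_and_rereference

STIM_WIN = (-0.5, 1.5)
RESP_WIN = (-1.5, 0.5)


@pytest.fixture(scope="session")
def small_config():
    """Two regions, one subject, realistic trial structure but short."""
    return synth.SimConfig(
        n_subjects=1, n_blocks_stroop=6, n_blocks_reading=3,
        electrodes_per_region={"ACC": 2, "dlPFC": 2, "null": 2},
        seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    """(trials, notch+CAR recording) for the single small subject."""
    trials, rec = synth.simulate_subject(small_config, 0)
    return trials, notch_and_rereference(rec)


@pytest.fixture(scope="session")
def small_tensors(small_cohort):
    """Stimulus- and response-aligned high-gamma tensors + I labels."""
    trials, rec = small_cohort
    ok = trials["correct"] & trials["rt"].notna()
    tri = trials[ok].reset_index(drop=True)
    ts = epoch_band_power(rec, tri, "high-gamma", "stimulus", STIM_WIN)
    tr = epoch_band_power(rec, tri, "high-gamma", "response", RESP_WIN)
    lab = (tri["congruency"] == "I").to_numpy()
    return tri, ts, tr, lab[ts.trial_index], lab[tr.trial_index]


def gaussian_tensor(rng, n_trials=60, n_bins=80, n_elec=1, smooth=20,
                    alignment="response", loc=100.0):
    """Synthetic null PowerTensor: positive, window-smoothed noise with
    the hop-grid autocorrelation the detector assumes (fast stand-in for
    the full signal pipeline in statistics-level tests)."""
    from conflictlfp.preprocess import PowerTensor
    raw = rng.standard_normal((n_elec, n_trials, n_bins + smooth))
    kern = np.ones(smooth) / smooth
    sm = np.apply_along_axis(np.convolve, 2, raw, kern, mode="valid")
    sm = sm[:, :, :n_bins]
    power = loc + 10.0 * sm
    t0 = -0.5 * n_bins * 0.01 if alignment == "response" else 0.0
    times = t0 + np.arange(n_bins) * 0.01
    return PowerTensor(
        power=power.astype(np.float32), times=times, alignment=alignment,
        band="high-gamma", baseline_mean=np.full(n_elec, loc),
        baseline_sd=np.full(n_elec, 10.0 / np.sqrt(smooth)),
        trial_index=np.arange(n_trials), electrodes=None)
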