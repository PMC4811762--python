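"""Sliding-F detector: oracles, run rule, bootstrap, calibration."""

import numpy as np
import pytest
import scipy.stats

from conflictlfp import selectivity as sel
from conflictlfp.preprocess import PowerTensor

from conftest import gaussian_tensor


# ---------------------------------------------------------------------------
# sliding F
# ---------------------------------------------------------------------------

def test_sliding_f_matches_brute_force_oracle():
    """Vectorised F equals scipy's one-way ANOVA bin by bin, and a
    hand-computed 6-trial case exactly."""
    rng = np.random.default_rng(0)
    power = rng.gamma(2.0, 5.0, size=(20, 15))
    labels = np.zeros(20, bool)
    labels[:8] = True
    f = sel.sliding_f(power, labels)
    for b in range(15):
        ref = scipy.stats.f_oneway(power[labels, b], power[~labels, b])
        assert np.isclose(f[b], ref.statistic, rtol=1e-10)

    # hand-computable toy: groups {1,2,3} vs {4,5,6} in one bin
    toy = np.array([[1.0], [2.0], [3.0], [4.0], [5.0], [6.0]])
    lab = np.array([True, True, True, False, False, False])
    # SSB = 3*(2-3.5)^2 + 3*(5-3.5)^2 = 13.5; SSW = 2+2 = 4; F = 13.5/1
    assert np.isclose(sel.sliding_f(toy, lab)[0], 13.5)


def test_sliding_f_invariant_to_trial_order():
    rng = np.random.default_rng(1)
    power = rng.gamma(2.0, 5.0, size=(30, 10))
    labels = rng.random(30) < 0.4
    f = sel.sliding_f(power, labels)
    perm = rng.permutation(30)
    f2 = sel.sliding_f(power[perm], labels[perm])
    assert np.allclose(f, f2, rtol=1e-5)


def test_sliding_f_requires_two_per_class():
    power = np.random.default_rng(2).random((5, 4))
    labels = np.array([True, False, False, False, False])
    with pytest.raises(sel.SelectivityError):
        sel.sliding_f(power, labels)


# ---------------------------------------------------------------------------
# permutation threshold
# ---------------------------------------------------------------------------

def test_threshold_alpha_half_is_null_median():
    rng = np.random.default_rng(3)
    power = rng.gamma(2.0, 5.0, size=(40, 6))
    labels = rng.random(40) < 0.4
    thr = sel.permutation_threshold(power, labels, alpha=0.5, n_perm=2000,
                                    rng=1)
    # median of the F(1, 38) null is ~0.46; permutation median matches
    ref = scipy.stats.f.ppf(0.5, 1, 38)
    assert np.allclose(thr, ref, rtol=0.25)


def test_threshold_deterministic_under_seed():
    rng = np.random.default_rng(4)
    power = rng.gamma(2.0, 5.0, size=(30, 8))
    labels = rng.random(30) < 0.4
    a = sel.permutation_threshold(power, labels, 0.01, 300, rng=7)
    b = sel.permutation_threshold(power, labels, 0.01, 300, rng=7)
    assert np.array_equal(a, b)


def test_threshold_rejects_low_n_perm():
    power = np.random.default_rng(5).random((20, 4))
    labels = np.arange(20) < 8
    with pytest.raises(sel.SelectivityError):
        sel.permutation_threshold(power, labels, 0.001, n_perm=50)


def test_per_bin_exceedance_matches_alpha():
    """On i.i.d. null data the observed F crosses its permutation
    threshold at close to the nominal rate (exchangeability)."""
    rng = np.random.default_rng(6)
    hits, total = 0, 0
    for _ in range(40):
        power = rng.gamma(2.0, 5.0, size=(24, 30))
        labels = np.arange(24) < 10
        f = sel.sliding_f(power, labels)
        thr = sel.permutation_threshold(power, labels, 0.05, 400, rng=rng)
        hits += int((f > thr).sum())
        total += 30
    rate = hits / total
    se = np.sqrt(0.05 * 0.95 / total)
    assert abs(rate - 0.05) < 4 * se


# ---------------------------------------------------------------------------
# detection rule
# ---------------------------------------------------------------------------

def _flat_tensor(n_bins=200, alignment="response", z_amp=3.0):
    """Tensor whose z-amplitude criterion is controllable."""
    rng = np.random.default_rng(7)
    t = gaussian_tensor(rng, n_trials=30, n_bins=n_bins,
                        alignment=alignment)
    if z_amp > 0:   # plant a mean offset so mean-z exceeds 1 somewhere
        t.power[:, :, n_bins // 2] += z_amp * t.baseline_sd[0]
    return t


def test_run_rule_four_bins_insufficient_five_enough():
    t = _flat_tensor()
    f = np.zeros(t.times.size)
    thr = np.ones(t.times.size)
    # the example divergence time snaps to the nearest 10 ms bin
    start = int(np.argmin(np.abs(t.times - (-0.669))))
    assert abs(t.times[start] - (-0.669)) <= 0.005

    f4 = f.copy()
    f4[start:start + 4] = 2.0
    r4 = sel.detect(t, f4, thr)
    assert not r4.selective

    f5 = f.copy()
    f5[start:start + 5] = 2.0
    r5 = sel.detect(t, f5, thr)
    assert r5.selective
    assert np.isclose(r5.latency, t.times[start])
    assert abs(r5.latency - (-0.669)) <= 0.005
    assert r5.pre_response


def test_amplitude_criterion_gates_selectivity():
    t = _flat_tensor(z_amp=0.0)
    f = np.zeros(t.times.size)
    f[100:110] = 5.0
    r = sel.detect(t, f, np.ones_like(f))
    assert not r.selective and not r.amplitude_ok


def test_detection_restricted_to_analysis_window():
    """Runs outside the response-aligned [-1, 0] s window do not fire."""
    t = _flat_tensor()
    f = np.zeros(t.times.size)
    late = np.searchsorted(t.times, 0.2)
    f[late:late + 10] = 5.0
    r = sel.detect(t, f, np.ones_like(f))
    assert not r.selective


def test_detect_length_mismatch_error():
    t = _flat_tensor()
    with pytest.raises(sel.SelectivityError):
        sel.detect(t, np.zeros(5), np.zeros(6))


# ---------------------------------------------------------------------------
# latency bootstrap
# ---------------------------------------------------------------------------

def test_latency_bootstrap_degenerate_step_and_guard():
    """A noiseless planted step bootstraps to zero s.e.m. at the step."""
    n_tr, n_bins = 24, 150
    power = np.full((n_tr, n_bins), 100.0, dtype=np.float32)
    labels = np.arange(n_tr) < 10
    start = 60
    power[labels, start:start + 40] += 50.0   # clean group difference
    t = PowerTensor(power=power[None, :, :],
                    times=-1.4 + np.arange(n_bins) * 0.01,
                    alignment="response", band="high-gamma",
                    baseline_mean=np.array([100.0]),
                    baseline_sd=np.array([1.0]),
                    trial_index=np.arange(n_tr))
    thr = np.full(n_bins, 1.0)
    mean, sem, lost = sel.latency_bootstrap(t, labels, thr, n_boot=50,
                                            rng=3)
    assert lost == 0.0
    assert sem < 1e-12
    assert np.isclose(mean, t.times[start])
    with pytest.raises(sel.SelectivityError):
        sel.latency_bootstrap(t, labels, thr, n_boot=1)


# ---------------------------------------------------------------------------
# population false positives / enrichment
# ---------------------------------------------------------------------------

def _null_population(rng, n_elec, n_trials=40, n_bins=120):
    tensors, labels = [], []
    for _ in range(n_elec):
        t = gaussian_tensor(rng, n_trials=n_trials, n_bins=n_bins,
                            alignment="response")
        t.power[:, :, 50] += 3.0 * t.baseline_sd[0]  # amplitude_ok
        tensors.append((t,))
        labels.append([rng.random(n_trials) < 0.4])
    return tensors, labels


def test_false_positive_rate_monotone_in_alpha_and_linear_in_size():
    rng = np.random.default_rng(8)
    tensors, labels = _null_population(rng, 24)
    loose, _, _, fired_loose = sel.estimate_false_positives(
        tensors, labels, n_shuffles=40, alpha=0.05, n_perm=200, rng=1,
        reuse_thresholds=True)
    tight, _, _, _ = sel.estimate_false_positives(
        tensors, labels, n_shuffles=40, alpha=0.002, n_perm=500, rng=1,
        reuse_thresholds=True)
    assert tight <= loose
    # doubling the population doubles the expected count
    half, _, _, _ = sel.estimate_false_positives(
        tensors[:12], labels[:12], n_shuffles=40, alpha=0.05, n_perm=200,
        rng=2, reuse_thresholds=True)
    assert abs(loose - 2 * half) < max(3.0, 0.75 * loose)


def test_false_positive_guards():
    rng = np.random.default_rng(9)
    tensors, labels = _null_population(rng, 3)
    with pytest.raises(sel.SelectivityError):
        sel.estimate_false_positives(tensors, labels, n_shuffles=5)
    with pytest.raises(sel.SelectivityError):
        sel.estimate_false_positives(tensors[:1], labels[:1],
                                     n_shuffles=10, n_perm=200)


def test_region_enrichment_extreme_and_calibrated():
    rng = np.random.default_rng(10)
    n_elec, n_shuf = 20, 60
    fired = rng.random((n_elec, n_shuf)) < 0.05
    regions = np.array(["A"] * 10 + ["B"] * 10)
    # all of region A observed selective -> p at the permutation floor
    selective = np.concatenate([np.ones(10, bool), np.zeros(10, bool)])
    table = sel.region_enrichment(selective, regions, fired)
    pa = table.set_index("region").loc["A", "p"]
    assert pa <= 1.0 / (n_shuf + 1) + 1e-12
    # a null observation is not enriched
    selective0 = np.zeros(n_elec, bool)
    table0 = sel.region_enrichment(selective0, regions, fired)
    assert (table0["p"] > 0.5).all()
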