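"""Single-electrode statistics: scalars, correlations, interaction,
Gratton controls and error monitoring."""

import numpy as np
import pytest

from conflictlfp import trial_stats as ts
from conflictlfp.preprocess import PowerTensor

from conftest import gaussian_tensor


def _tensor_from(power, alignment="response"):
    n_tr, n_bins = power.shape
    t0 = -1.4 if alignment == "response" else -0.4
    return PowerTensor(power=power[None].astype(np.float32),
                       times=t0 + np.arange(n_bins) * 0.01,
                       alignment=alignment, band="high-gamma",
                       baseline_mean=np.array([power.mean()]),
                       baseline_sd=np.array([1.0]),
                       trial_index=np.arange(n_tr))


def test_single_trial_power_constant_and_spike():
    const = _tensor_from(np.full((10, 160), 7.0))
    mx = ts.single_trial_power(const, mode="max")
    mn = ts.single_trial_power(const, mode="mean")
    assert np.allclose(mx.values, 7.0) and np.allclose(mn.values, 7.0)

    spiky = np.full((4, 160), 1.0)
    peak_bin = 80
    spiky[:, peak_bin] = 101.0
    t = _tensor_from(spiky)
    mx = ts.single_trial_power(t, mode="max")
    mn = ts.single_trial_power(t, mode="mean")
    n_win = ((t.times >= -1) & (t.times <= 0)).sum()
    assert np.allclose(mx.values, 101.0)
    assert np.allclose(mn.values, 1.0 + 100.0 / n_win)
    assert np.allclose(mx.peak_times, t.times[peak_bin])


def test_max_and_mean_modes_agree_on_burst_data():
    """On burst-like trials the two scalar definitions rank trials
    similarly (the analyses are robust to the choice)."""
    rng = np.random.default_rng(0)
    gains = rng.lognormal(0, 0.4, 80)
    prof = np.exp(-0.5 * ((np.arange(160) - 90) / 12.0) ** 2)
    power = 10 + gains[:, None] * 40 * prof[None, :] + \
        rng.standard_normal((80, 160))
    t = _tensor_from(power)
    mx = ts.single_trial_power(t, mode="max").values
    mn = ts.single_trial_power(t, mode="mean").values
    assert np.corrcoef(mx, mn)[0, 1] > 0.8


def test_power_rt_correlation_limits():
    rng = np.random.default_rng(1)
    rts = rng.lognormal(0, 0.2, 60)
    # perfectly linear relation
    r, p = ts.power_rt_correlation(2.0 * rts + 1.0, rts, n_perm=500, rng=2)
    assert np.isclose(r, 1.0)
    assert p == pytest.approx(1.0 / 501)
    # broken pairing
    r0, p0 = ts.power_rt_correlation(rng.permutation(rts), rts,
                                     n_perm=500, rng=3)
    assert abs(r0) < 0.35 and p0 > 0.01
    with pytest.raises(ts.TrialStatsError):
        ts.power_rt_correlation(np.ones(30), rts[:30], 100, 1)
    with pytest.raises(ts.TrialStatsError):
        ts.power_rt_correlation(rts[:5], rts[:5], 100, 1)


def test_interaction_f_matches_closed_form_oracle():
    """Balanced 2x2 with n=3 per cell against the textbook two-way ANOVA
    decomposition, exact."""
    y = np.array([3.0, 4.0, 5.0,   6.0, 7.0, 8.0,
                  2.0, 3.0, 4.0,   10.0, 11.0, 15.0])
    cong = np.array([0, 0, 0, 1, 1, 1, 0, 0, 0, 1, 1, 1])
    task = np.array([0, 0, 0, 0, 0, 0, 1, 1, 1, 1, 1, 1])

    # closed form: cell means, balanced design
    cells = {(c_, t_): y[(cong == c_) & (task == t_)]
             for c_ in (0, 1) for t_ in (0, 1)}
    n = 3
    grand = y.mean()
    c_m = {c_: y[cong == c_].mean() for c_ in (0, 1)}
    t_m = {t_: y[task == t_].mean() for t_ in (0, 1)}
    ss_int = sum(n * (cells[c_, t_].mean() - c_m[c_] - t_m[t_] + grand) ** 2
                 for c_ in (0, 1) for t_ in (0, 1))
    ss_err = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    f_expected = (ss_int / 1.0) / (ss_err / (12 - 4))

    f = ts._interaction_f_bins(y[:, None], cong, task)[0]
    assert np.isclose(f, f_expected, rtol=1e-12)


def test_interaction_peak_detects_stroop_only_effect():
    """A congruency effect present in one task only yields a significant
    Congruency x Task interaction."""
    rng = np.random.default_rng(4)
    n_per, n_bins = 40, 60
    times = -0.6 + np.arange(n_bins) * 0.01
    prof = np.exp(-0.5 * ((times + 0.3) / 0.08) ** 2)
    rows, cong, task = [], [], []
    for t_ in (0, 1):
        for c_ in (0, 1):
            base = 10 + rng.standard_normal((n_per, n_bins))
            if t_ == 1 and c_ == 1:     # Stroop incongruent only
                base += 3.0 * prof[None, :]
            rows.append(base)
            cong += [c_] * n_per
            task += [t_] * n_per
    power = np.vstack(rows)
    fpk, p = ts.interaction_peak_f(power, np.array(cong), np.array(task),
                                   times, pre_window=(-0.6, 0.0),
                                   n_perm=500, rng=5)
    assert p < 0.01
    # additive effect (same in both tasks) stays null
    rows2 = []
    for t_ in (0, 1):
        for c_ in (0, 1):
            base = 10 + rng.standard_normal((n_per, n_bins))
            if c_ == 1:
                base += 3.0 * prof[None, :]
            rows2.append(base)
    _, p0 = ts.interaction_peak_f(np.vstack(rows2), np.array(cong),
                                  np.array(task), times,
                                  pre_window=(-0.6, 0.0), n_perm=300,
                                  rng=6)
    assert p0 > 0.05
    with pytest.raises(ts.TrialStatsError):
        ts.interaction_peak_f(power, np.ones_like(cong), np.array(task),
                              times, (-0.6, 0.0), 100, 1)


def _gratton_data(rng, n=120, beta_rt=0.0, delta=0.0, rt_shift=0.034):
    hist = np.where(rng.random(n) < 0.6, "cI", "iI")
    rt = rng.lognormal(0, 0.2, n) + np.where(hist == "cI", rt_shift, 0.0)
    power = 20 + beta_rt * rt + np.where(hist == "cI", delta, 0.0) + \
        rng.standard_normal(n)
    return power, hist, rt


def test_ancova_removes_pure_rt_confound():
    """Power depends on RT only; cI trials are slower, so the raw
    contrast is biased but the RT-adjusted contrast vanishes."""
    rng = np.random.default_rng(7)
    power, hist, rt = _gratton_data(rng, n=4000, beta_rt=8.0, delta=0.0,
                                    rt_shift=0.2)
    raw = ts.gratton_contrast(power, hist)
    adj, _ = ts.gratton_ancova(power, hist, rt)
    assert raw > 3 * abs(adj)
    assert abs(adj) < 0.15


def test_ancova_recovers_planted_history_effect():
    rng = np.random.default_rng(8)
    power, hist, rt = _gratton_data(rng, n=3000, beta_rt=8.0, delta=1.5,
                                    rt_shift=0.2)
    adj, p = ts.gratton_ancova(power, hist, rt)
    assert abs(adj - 1.5) < 0.2
    assert p < 1e-6


def test_ancova_zero_slope_reduces_to_raw_difference():
    rng = np.random.default_rng(9)
    power, hist, rt = _gratton_data(rng, n=500, beta_rt=0.0, delta=0.7)
    raw = ts.gratton_contrast(power, hist)
    adj, _ = ts.gratton_ancova(power, hist, rt)
    assert abs(adj - raw) < 0.1


def test_ancova_guards():
    rng = np.random.default_rng(10)
    power, hist, rt = _gratton_data(rng, n=30)
    with pytest.raises(ts.TrialStatsError):
        ts.gratton_ancova(power[:8], hist[:8], np.full(8, 1.0))
    hist_few = np.array(["cI"] * 27 + ["iI"] * 3)
    with pytest.raises(ts.TrialStatsError):
        ts.gratton_ancova(power, hist_few, rt)


def test_rt_matching_identical_distributions_keep_everything():
    rng = np.random.default_rng(11)
    n = 400
    hist = np.where(np.arange(n) % 2 == 0, "cI", "iI")
    rt = np.tile(rng.lognormal(0, 0.2, n // 2), 2)
    power = 20 + rng.standard_normal(n)
    contrast, retention, kept = ts.rt_matched_subsample(power, hist, rt,
                                                        rng=12)
    assert retention > 0.9
    raw = ts.gratton_contrast(power, hist)
    assert abs(contrast - raw) < 0.3


def test_rt_matching_equalises_group_rts():
    rng = np.random.default_rng(13)
    power, hist, rt = _gratton_data(rng, n=600, rt_shift=0.215)
    _, retention, kept = ts.rt_matched_subsample(power, hist, rt, rng=14)
    assert retention < 1.0
    ra = rt[kept][hist[kept] == "cI"]
    rb = rt[kept][hist[kept] == "iI"]
    assert abs(ra.mean() - rb.mean()) < 0.2  # below one bin width


def test_error_monitoring_contrast_and_guards():
    rng = np.random.default_rng(15)
    # planted post-error increase, n=11 self-corrections
    post_err = 2.0 + 0.5 * rng.standard_normal(11)
    post_corr = 0.0 + 0.5 * rng.standard_normal(11)
    eff, p = ts.error_monitoring(post_err, post_corr)
    assert eff > 1.0 and p <= 0.01
    # identical signals: no effect
    same = rng.standard_normal(12)
    eff0, p0 = ts.error_monitoring(same, same + 1e-12 *
                                   rng.standard_normal(12))
    assert abs(eff0) < 1e-9 and p0 > 0.2
    # too few trials -> skipped
    assert ts.error_monitoring(post_err[:4], post_corr[:4]) is None
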