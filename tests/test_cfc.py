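"""Phase-amplitude coupling: filters, Modulation Index, surrogates."""

import numpy as np
import pytest
import scipy.signal

from conflictlfp import cfc, synth


def test_fir_filter_is_zero_phase():
    """A symmetric pulse keeps its center of mass after filtering."""
    fs = 500.0
    n = 4000
    x = np.exp(-0.5 * ((np.arange(n) - 2000) / 30.0) ** 2)
    x = x * np.sin(2 * np.pi * 6.0 * np.arange(n) / fs)
    taps = cfc.design_fir((4.0, 8.0), fs)
    y = cfc._zero_phase(x, taps)
    com_x = (np.abs(scipy.signal.hilbert(x)) * np.arange(n)).sum() / \
        np.abs(scipy.signal.hilbert(x)).sum()
    com_y = (np.abs(scipy.signal.hilbert(y)) * np.arange(n)).sum() / \
        np.abs(scipy.signal.hilbert(y)).sum()
    assert abs(com_x - com_y) < 5.0  # samples


def test_phase_advances_at_carrier_frequency():
    fs = 500.0
    t = np.arange(int(20 * fs)) / fs
    x = np.sin(2 * np.pi * 6.0 * t)
    phase, _ = cfc.phase_amplitude(x, fs)
    cycles = np.unwrap(phase)[2500:-2500]
    rate = (cycles[-1] - cycles[0]) / (len(cycles) / fs) / (2 * np.pi)
    assert abs(rate - 6.0) < 0.05


def test_unmodulated_tone_amplitude_constant():
    fs = 500.0
    t = np.arange(int(10 * fs)) / fs
    x = np.sin(2 * np.pi * 100.0 * t)
    _, amp = cfc.phase_amplitude(x, fs)
    inner = amp[1000:-1000]
    assert inner.std() / inner.mean() < 0.05


def test_too_short_signal_rejected():
    with pytest.raises(cfc.CFCError):
        cfc.phase_amplitude(np.zeros(100), 500.0)


def test_mi_analytic_limits():
    rng = np.random.default_rng(0)
    phase = rng.uniform(-np.pi, np.pi, 20000)
    # uniform amplitude -> MI = 0 exactly
    assert cfc.modulation_index(phase, np.ones_like(phase)).mi == \
        pytest.approx(0.0, abs=1e-12)
    # all amplitude mass in one bin -> MI = 1
    amp = np.where((phase > 0) & (phase < 2 * np.pi / 18), 1.0, 0.0)
    assert cfc.modulation_index(phase, amp).mi == pytest.approx(1.0)


def test_mi_matches_direct_kl_oracle():
    """amp = 1 + cos(phase) with N = 18 bins: MI equals the KL distance
    computed directly from the binned distribution."""
    rng = np.random.default_rng(1)
    phase = rng.uniform(-np.pi, np.pi, 200000)
    amp = 1.0 + np.cos(phase)
    res = cfc.modulation_index(phase, amp, n_bins=18)
    edges = np.linspace(-np.pi, np.pi, 19)
    idx = np.clip(np.digitize(phase, edges) - 1, 0, 17)
    means = np.array([amp[idx == j].mean() for j in range(18)])
    p = means / means.sum()
    kl = np.sum(p * np.log(p * 18))
    assert np.isclose(res.mi, kl / np.log(18), atol=1e-12)
    assert np.isclose(res.amp_means.sum() / res.amp_means.sum(), 1.0)


def test_mi_invariances():
    rng = np.random.default_rng(2)
    phase = rng.uniform(-np.pi, np.pi, 50000)
    amp = 1.0 + 0.4 * np.cos(phase) + 0.05 * rng.random(50000)
    mi0 = cfc.modulation_index(phase, amp).mi
    # amplitude rescaling
    assert np.isclose(cfc.modulation_index(phase, 7.3 * amp).mi, mi0,
                      atol=1e-12)
    # phase rotation (circular shift of bin labels)
    rot = np.angle(np.exp(1j * (phase + 2 * np.pi * 3 / 18)))
    mi_rot = cfc.modulation_index(rot, amp).mi
    assert np.isclose(mi_rot, mi0, atol=1e-3)


def test_surrogate_test_detects_planted_coupling():
    cfg = synth.SimConfig(n_subjects=1, n_blocks_stroop=5,
                          electrodes_per_region={"ACC": 1},
                          pac_strength=0.5)
    _, rec = synth.simulate_subject(cfg, 0)
    x = rec.signal[0][:int(100 * rec.fs)]
    phase, amp = cfc.phase_amplitude(x, rec.fs)
    res = cfc.mi_surrogate_test(phase, amp, rec.fs, n_surr=1000, rng=3)
    assert res.p <= 0.001
    # uncoupled channel stays at chance
    cfg0 = synth.SimConfig(n_subjects=1, n_blocks_stroop=5,
                           electrodes_per_region={"ACC": 1},
                           pac_strength=0.0)
    _, rec0 = synth.simulate_subject(cfg0, 0)
    ph0, am0 = cfc.phase_amplitude(rec0.signal[0][:int(100 * rec0.fs)],
                                   rec0.fs)
    res0 = cfc.mi_surrogate_test(ph0, am0, rec0.fs, n_surr=200, rng=4)
    assert res0.p > 0.01


def test_estimators_rank_concordant_across_depths():
    """MI and the mean-vector-length estimator order planted coupling
    depths {0, 0.25, 0.5, 0.75} identically."""
    mis, mvls = [], []
    for d in (0.0, 0.25, 0.5, 0.75):
        cfg = synth.SimConfig(n_subjects=1, n_blocks_stroop=3,
                              electrodes_per_region={"ACC": 1},
                              pac_strength=d)
        _, rec = synth.simulate_subject(cfg, 0)
        x = rec.signal[0][:int(60 * rec.fs)]
        phase, amp = cfc.phase_amplitude(x, rec.fs)
        mis.append(cfc.modulation_index(phase, amp).mi)
        mvls.append(cfc.mean_vector_length(phase, amp))
    assert np.all(np.diff(mis) > 0)
    assert np.all(np.diff(mvls) > 0)


def test_trial_swap_surrogates_calibrated_on_null():
    rng = np.random.default_rng(5)
    phases = [rng.uniform(-np.pi, np.pi, 800) for _ in range(20)]
    amps = [1 + 0.2 * rng.random(800) for _ in range(20)]
    res = cfc.trial_swap_surrogate_test(phases, amps, n_surr=200, rng=6)
    assert res.p > 0.01


def test_condition_difference_same_data_is_zero():
    rng = np.random.default_rng(7)
    phases = [rng.uniform(-np.pi, np.pi, 500) for _ in range(15)]
    amps = [1 + rng.random(500) for _ in range(15)]
    delta, p = cfc.mi_condition_difference(phases, amps, phases, amps,
                                           n_perm=200, rng=8)
    assert delta == pytest.approx(0.0, abs=1e-12)
    assert p > 0.5


def test_condition_difference_detects_one_sided_coupling():
    rng = np.random.default_rng(9)
    n_tr, n_samp = 30, 1500
    phases_c, amps_c, phases_i, amps_i = [], [], [], []
    for _ in range(n_tr):
        ph = np.angle(np.exp(1j * np.cumsum(
            2 * np.pi * 6 / 500 * np.ones(n_samp)) + rng.uniform(0, 7)))
        phases_c.append(ph)
        phases_i.append(np.roll(ph, rng.integers(50, 400)))
        amps_c.append(1 + 0.1 * rng.random(n_samp))
        amps_i.append((1 + 0.8 * np.cos(phases_i[-1])) *
                      (1 + 0.1 * rng.random(n_samp)))
    delta, p = cfc.mi_condition_difference(phases_c, amps_c, phases_i,
                                           amps_i, n_perm=300, rng=10)
    assert delta > 0
    assert p < 0.01
    with pytest.raises(cfc.CFCError):
        cfc.mi_condition_difference(phases_c[:5], amps_c[:5], phases_i,
                                    amps_i, 100, 1)
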