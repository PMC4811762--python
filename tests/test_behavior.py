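"""Short-time energy, speech-onset detection and behavioral summaries."""

import numpy as np
import pandas as pd
import pytest
import scipy.signal
from hypothesis import given, settings
from hypothesis import strategies as st

from conflictlfp import behavior, synth

FS = 8192.0


def test_short_time_energy_zero_and_homogeneity():
    x = np.zeros(2000)
    assert np.allclose(behavior.short_time_energy(x, FS).e, 0.0)
    rng = np.random.default_rng(0)
    y = rng.standard_normal(3000)
    e1 = behavior.short_time_energy(y, FS).e
    e3 = behavior.short_time_energy(3.0 * y, FS).e
    assert np.allclose(e3, 9.0 * e1, rtol=1e-10)


def test_short_time_energy_impulse_is_squared_window():
    """A unit impulse at sample k reproduces the squared Hamming taper
    starting at k (convolution identity)."""
    k = 700
    x = np.zeros(2000)
    x[k] = 1.0
    e = behavior.short_time_energy(x, FS).e
    w2 = scipy.signal.windows.hamming(300, sym=True) ** 2
    expect = np.zeros(2000)
    expect[k:k + 300] = w2
    assert np.allclose(e, expect, atol=1e-12)


def test_short_audio_rejected():
    with pytest.raises(behavior.BehaviorError):
        behavior.short_time_energy(np.zeros(100), FS)


@settings(max_examples=20, deadline=None)
@given(shift=st.integers(min_value=0, max_value=2000),
       scale=st.floats(min_value=0.25, max_value=8.0))
def test_onset_detection_shift_equivariant_scale_invariant(shift, scale):
    """Detected onset shifts with the burst and ignores overall gain."""
    rng = np.random.default_rng(99)
    fs = FS
    n = int(3.0 * fs)
    base = 0.01 * rng.standard_normal(n)
    k0 = int(1.0 * fs)
    burst = 0.5 * np.sin(2 * np.pi * 300 * np.arange(2000) / fs)
    x = base.copy()
    x[k0 + shift:k0 + shift + 2000] += burst
    tr = behavior.short_time_energy(scale * x, fs)
    onset = behavior.detect_speech_onset(tr, stim_onset_s=0.5)
    assert onset is not None
    expect = (k0 + shift) / fs - 0.5
    assert abs(onset - expect) < 0.04  # one energy-window length


def test_planted_onset_recovered_and_missing_cases():
    cfg = synth.SimConfig(n_blocks_stroop=3)
    trials = synth.make_trial_table(cfg, "Stroop", 11)
    traces = synth.synthesize_audio(trials, FS, 12)
    out = behavior.rts_from_audio(trials, traces, FS)
    ok = out["rt"].notna() & ~out["self_corrected"]
    err = (out.loc[ok, "rt_detected"] - out.loc[ok, "rt"]).abs()
    assert err.max() < 0.04
    # no-response trials stay missing
    miss = out["rt"].isna()
    if miss.any():
        assert out.loc[miss, "rt_detected"].isna().all()
    assert (out.loc[ok, "n_bursts"] == 1).all()


def test_self_correction_trials_have_two_ordered_bursts():
    cfg = synth.SimConfig(n_blocks_stroop=6, error_rate_incongruent=0.6,
                          p_self_correct_given_error=1.0)
    trials = synth.make_trial_table(cfg, "Stroop", 21)
    sc = trials[trials["self_corrected"]]
    assert len(sc) >= 3
    traces = synth.synthesize_audio(trials, FS, 22)
    for i in sc.index[:5]:
        tr = behavior.short_time_energy(np.asarray(traces[i]), FS)
        bursts = behavior.detect_bursts(tr, stim_onset_s=0.5,
                                        baseline_s=0.5)
        assert len(bursts) == 2
        assert bursts[0] < bursts[1]
        assert abs(bursts[0] - (trials.loc[i, "error_response_onset"] -
                                trials.loc[i, "stimulus_onset"])) < 0.04


def test_silent_trace_missing_constant_trace_degenerate():
    e_silent = behavior.short_time_energy(np.zeros(3000), FS)
    assert behavior.detect_speech_onset(e_silent, 0.2) is None
    const = behavior.EnergyTrace(e=np.full(3000, 2.0), fs_audio=FS,
                                 baseline=(2.0, 0.0))
    with pytest.raises(behavior.BehaviorError):
        behavior.detect_speech_onset(const, 0.2)


def _seq_table(congruencies, block=0):
    n = len(congruencies)
    words = ["Red", "Blue", "Green", "Red", "Blue", "Green"] * 5
    return pd.DataFrame({
        "trial_id": range(n), "block_id": block, "task": "Stroop",
        "word": words[:n],
        "color": ["red" if c == "C" else "blue" for c in congruencies],
        "congruency": list(congruencies)})


def test_history_definition_and_idempotence():
    t = behavior.label_history(_seq_table("CII"))
    assert t["history"].tolist() == ["undefined", "cI", "iI"]
    t2 = behavior.label_history(t)
    assert t2["history"].tolist() == t["history"].tolist()
    assert not t["stim_repeat"].iloc[0]


def test_history_resets_at_block_boundary():
    a = _seq_table("CI", block=0)
    b = _seq_table("IC", block=1)
    b["trial_id"] += 2
    t = behavior.label_history(pd.concat([a, b], ignore_index=True))
    assert t["history"].tolist() == ["undefined", "cI", "undefined", "iC"]


def test_stimulus_repeats_flagged():
    t = pd.DataFrame({
        "trial_id": [0, 1, 2], "block_id": 0, "task": "Stroop",
        "word": ["Red", "Red", "Blue"], "color": ["blue", "blue", "red"],
        "congruency": ["I", "I", "I"]})
    out = behavior.label_history(t)
    assert out["stim_repeat"].tolist() == [False, True, False]


def test_zscored_rts_per_subject_standardised():
    cfg = synth.SimConfig(n_blocks_stroop=6)
    rows = [synth.make_trial_table(cfg, "Stroop", 30 + s).assign(subject=s)
            for s in range(3)]
    t = behavior.zscore_rts(pd.concat(rows, ignore_index=True))
    ok = t["correct"] & t["rt"].notna() & ~t["self_corrected"]
    g = t[ok].groupby("subject")["rt_z"]
    assert np.allclose(g.mean(), 0.0, atol=1e-10)
    assert np.allclose(g.std(), 1.0, atol=1e-10)


def test_behavioral_summary_recovers_planted_effects():
    """Cohort-level congruency delay and Gratton contrasts recover the
    planted 215 / 34 / 72 ms values within 3 s.e. of the across-subject
    mean."""
    cfg = synth.SimConfig()
    rows = []
    for s in range(cfg.n_subjects):
        for task in ("Stroop", "Reading"):
            tt = synth.make_trial_table(
                cfg, task, np.random.default_rng(500 + 2 * s +
                                                 (task == "Reading")))
            rows.append(tt.assign(subject=s))
    summ = behavior.behavioral_summary(pd.concat(rows, ignore_index=True))
    for key, planted in (("congruency_delay_stroop", 0.215),
                         ("gratton_cI_minus_iI", 0.034),
                         ("gratton_iC_minus_cC", 0.072)):
        got = summ[key]
        sem = got["sd"] / np.sqrt(got["n"])
        assert abs(got["mean"] - planted) < 3 * sem, key
    assert summ["congruency_delay_stroop"]["t_p"] < 0.001
    err = summ["error_rates"]
    stroop_err = err[err["task"] == "Stroop"]["error_rate"].mean()
    assert abs(stroop_err - 0.05) < 0.03


def test_null_generator_gives_null_summary():
    cfg = synth.SimConfig(rt_congruency_delay=0.0,
                          rt_gratton_cI_minus_iI=0.0,
                          rt_gratton_iC_minus_cC=0.0, n_blocks_stroop=9)
    rows = [synth.make_trial_table(cfg, "Stroop",
                                   np.random.default_rng(900 + s)
                                   ).assign(subject=s) for s in range(8)]
    summ = behavior.behavioral_summary(pd.concat(rows, ignore_index=True))
    got = summ["congruency_delay_stroop"]
    sem = got["sd"] / np.sqrt(got["n"])
    assert abs(got["mean"]) < 3 * sem


def test_summary_requires_multiple_subjects():
    cfg = synth.SimConfig(n_blocks_stroop=2)
    t = synth.make_trial_table(cfg, "Stroop", 1).assign(subject=0)
    with pytest.raises(behavior.BehaviorError):
        behavior.behavioral_summary(t)
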