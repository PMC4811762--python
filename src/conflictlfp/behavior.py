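"""Reaction times from audio and behavioral summary statistics.

Speech onset is detected from the short-time energy of the microphone
trace,

    E(t) = sum_m [x(m) w(t - m)]^2,

with ``w`` a 300-point Hamming taper (~40 ms at 8192 Hz): the squared
signal convolved with the squared taper.  Onset is the first time the
energy crosses one standard deviation above the pre-stimulus baseline.
A trial counts as a single verbal response when exactly one
supra-threshold burst is found (burst segmentation uses hysteresis: a
burst ends when the energy falls below baseline mean + 0.5 s.d.).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal
import scipy.stats

ENERGY_WINDOW = 300         # samples
BASELINE_S = 0.5            # pre-stimulus audio baseline


class BehaviorError(ValueError):
    pass


@dataclass
class EnergyTrace:
    e: np.ndarray               # per-sample short-time energy, >= 0
    fs_audio: float
    window: int = ENERGY_WINDOW
    baseline: tuple[float, float] | None = None   # (mean, sd)


def short_time_energy(audio: np.ndarray, fs_audio: float,
                      window: int = ENERGY_WINDOW) -> EnergyTrace:
    """Short-time energy of a mono PCM trace (same length as the input)."""
    x = np.asarray(audio, dtype=float)
    if x.ndim != 1:
        raise BehaviorError("audio must be a 1-D mono trace")
    if x.size < window:
        raise BehaviorError(f"audio shorter than the {window}-sample window")
    w2 = scipy.signal.windows.hamming(window, sym=True) ** 2
    e = scipy.signal.fftconvolve(x ** 2, w2, mode="full")[:x.size]
    return EnergyTrace(e=np.maximum(e, 0.0), fs_audio=fs_audio,
                       window=window)


def _baseline_stats(trace: EnergyTrace, stim_onset_s: float,
                    baseline_s: float = BASELINE_S):
    if trace.baseline is not None:
        return trace.baseline
    s1 = int(round(stim_onset_s * trace.fs_audio))
    # skip the first window-length of the trace: the convolution ramp-up
    # would otherwise inflate the baseline s.d.
    s0 = max(trace.window, s1 - int(round(baseline_s * trace.fs_audio)))
    if s1 - s0 < trace.window:
        raise BehaviorError("baseline interval shorter than energy window")
    seg = trace.e[s0:s1]
    return float(seg.mean()), float(seg.std())


#: a supra-threshold excursion only counts as speech when its peak also
#: clears this many baseline s.d. (speech energy is orders of magnitude
#: above the noise floor; stationary-noise excursions above +1 s.d. are
#: frequent but never reach this level)
BURST_PEAK_SD = 20.0


def _check_baseline(e: np.ndarray, mean: float, sd: float):
    if sd <= 0:
        if np.allclose(e, 0):
            return None  # silent trace: nothing to detect
        raise BehaviorError("degenerate (zero-s.d.) energy baseline")
    return mean, sd


def _burst_segments(e: np.ndarray, mean: float, sd: float):
    """(onset, offset) sample pairs of speech bursts after the stimulus.

    A burst opens at the first crossing of mean + 1 s.d., closes when E
    falls below mean + 0.5 s.d. (hysteresis), and is only kept when its
    peak exceeds mean + BURST_PEAK_SD s.d.
    """
    hi = mean + sd
    lo = mean + 0.5 * sd
    above = e > hi
    if not above.any():
        return []
    d = np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    # merge excursions separated only by a dip that stays above ``lo``
    merged = []
    for s0, s1 in zip(starts, ends):
        if merged and not np.any(e[merged[-1][1]:s0] < lo):
            merged[-1] = (merged[-1][0], s1)
        else:
            merged.append((s0, s1))
    peak = mean + BURST_PEAK_SD * sd
    return [(s0, s1) for s0, s1 in merged if e[s0:s1].max() > peak]


def detect_speech_onset(trace: EnergyTrace, stim_onset_s: float = 0.0,
                        baseline_s: float = BASELINE_S) -> float | None:
    """Speech onset in seconds after stimulus onset, or ``None``.

    Onset is the first time the energy crosses one standard deviation
    above the pre-stimulus baseline within an excursion whose peak
    clears the speech level (see ``BURST_PEAK_SD``); a silent or
    never-crossing trace reports a missing onset.
    """
    mean, sd = _baseline_stats(trace, stim_onset_s, baseline_s)
    checked = _check_baseline(trace.e, mean, sd)
    if checked is None:
        return None
    s1 = int(round(stim_onset_s * trace.fs_audio))
    segs = _burst_segments(trace.e[s1:], mean, sd)
    if not segs:
        return None
    return segs[0][0] / trace.fs_audio


def detect_bursts(trace: EnergyTrace, stim_onset_s: float = 0.0,
                  baseline_s: float = BASELINE_S) -> list[float]:
    """Onset times (s after stimulus) of all detected speech bursts."""
    mean, sd = _baseline_stats(trace, stim_onset_s, baseline_s)
    checked = _check_baseline(trace.e, mean, sd)
    if checked is None:
        return []
    s1 = int(round(stim_onset_s * trace.fs_audio))
    segs = _burst_segments(trace.e[s1:], mean, sd)
    return [s0 / trace.fs_audio for s0, _ in segs]


def label_history(trials: pd.DataFrame) -> pd.DataFrame:
    """Add trial-history (cC/iC/cI/iI) and stimulus-repeat labels.

    History encodes the previous trial's congruency followed by the
    current one (e.g. ``cI`` = incongruent preceded by congruent); the
    first trial of each block is ``undefined`` — history does not cross
    block boundaries.  ``stim_repeat`` flags trials whose word-color
    pair repeats the immediately preceding trial (such trials are
    excluded from Gratton analyses).  Idempotent.
    """
    t = trials.copy()
    if not t["trial_id"].is_monotonic_increasing:
        raise BehaviorError("trials must be in presentation order")
    prev = t["congruency"].shift(1)
    same_block = t["block_id"].eq(t["block_id"].shift(1))
    hist = prev.str.lower() + t["congruency"]
    t["history"] = hist.where(same_block, "undefined")
    t["history"] = t["history"].fillna("undefined")
    t["stim_repeat"] = (same_block &
                        t["word"].eq(t["word"].shift(1)) &
                        t["color"].eq(t["color"].shift(1)))
    return t


def rts_from_audio(trials: pd.DataFrame, traces: list[np.ndarray],
                   fs_audio: float, pre_stim: float = 0.5) -> pd.DataFrame:
    """Detect per-trial speech onsets and burst counts from audio.

    The audio traces start ``pre_stim`` seconds before stimulus onset;
    the energy baseline is the pre-stimulus interval.  Trials with zero
    or multiple bursts fail the single-response rule
    (``single_response`` column).
    """
    out = trials.copy()
    rts, n_bursts = [], []
    for x in traces:
        tr = short_time_energy(np.asarray(x), fs_audio)
        onset = detect_speech_onset(tr, stim_onset_s=pre_stim,
                                    baseline_s=pre_stim)
        bursts = detect_bursts(tr, stim_onset_s=pre_stim,
                               baseline_s=pre_stim)
        rts.append(np.nan if onset is None else onset)
        n_bursts.append(len(bursts))
    out["rt_detected"] = rts
    out["n_bursts"] = n_bursts
    out["single_response"] = np.array(n_bursts) == 1
    return out


def zscore_rts(trials: pd.DataFrame) -> pd.DataFrame:
    """Within-subject z-scored RTs over that subject's correct trials."""
    t = trials.copy()
    grp = ["subject", "task"] if "subject" in t else ["task"]
    def _z(g):
        ok = g["correct"] & g["rt"].notna() & ~g["self_corrected"]
        m, s = g.loc[ok, "rt"].mean(), g.loc[ok, "rt"].std()
        return (g["rt"] - m) / s
    t["rt_z"] = t.groupby(grp, group_keys=False).apply(_z, include_groups=False)
    return t


def behavioral_summary(trials: pd.DataFrame) -> dict:
    """Per-subject congruency and Gratton RT effects with paired tests.

    Expects a concatenated multi-subject trial table with a ``subject``
    column.  RT summaries use correct, non-self-corrected trials;
    Gratton contrasts additionally drop stimulus repetitions.  Returns
    per-subject means plus paired t and signed-rank tests across
    subjects for the congruency delay and both history contrasts.
    """
    if "subject" not in trials.columns:
        raise BehaviorError("multi-subject table with 'subject' required")
    if trials["subject"].nunique() < 2:
        raise BehaviorError("need >= 2 subjects for across-subject tests")
    t = trials[trials["correct"] & trials["rt"].notna() &
               ~trials["self_corrected"]].copy()
    if t.empty:
        raise BehaviorError("no correct trials")

    per, gr = [], []
    for subj, g in t.groupby("subject"):
        row = {"subject": subj}
        for task, gg in g.groupby("task"):
            c = gg.loc[gg["congruency"] == "C", "rt"].mean()
            i = gg.loc[gg["congruency"] == "I", "rt"].mean()
            row[f"delay_{task}"] = i - c
        per.append(row)
        gng = g[(g["task"] == "Stroop") & ~g["stim_repeat"]]
        h = gng.groupby("history")["rt"].mean()
        gr.append({"subject": subj,
                   "cI_minus_iI": h.get("cI", np.nan) - h.get("iI", np.nan),
                   "iC_minus_cC": h.get("iC", np.nan) - h.get("cC", np.nan)})
    per = pd.DataFrame(per)
    gr = pd.DataFrame(gr)

    errors = (trials[trials["congruency"] == "I"]
              .groupby(["subject", "task"])["correct"]
              .apply(lambda s: 1.0 - s.mean()).rename("error_rate")
              .reset_index())

    def _paired(vals):
        v = np.asarray(vals, float)
        v = v[np.isfinite(v)]
        if v.size < 2 or np.allclose(v, v[0]):
            return {"mean": float(np.mean(v)) if v.size else np.nan,
                    "t_p": np.nan, "signrank_p": np.nan, "n": int(v.size)}
        tt = scipy.stats.ttest_1samp(v, 0.0)
        try:
            wr = scipy.stats.wilcoxon(v)
            wp = float(wr.pvalue)
        except ValueError:
            wp = np.nan
        return {"mean": float(v.mean()), "sd": float(v.std(ddof=1)),
                "t_p": float(tt.pvalue), "signrank_p": wp, "n": int(v.size)}

    summary = {
        "per_subject": per,
        "gratton_per_subject": gr,
        "error_rates": errors,
        "congruency_delay_stroop": _paired(per.get("delay_Stroop", [])),
        "congruency_delay_reading": _paired(per.get("delay_Reading", [])),
        "gratton_cI_minus_iI": _paired(gr["cI_minus_iI"]),
        "gratton_iC_minus_cC": _paired(gr["iC_minus_cC"]),
    }
    return summary
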