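"""Conflict-selectivity detection: sliding F, permutation thresholds,
run-length rule, latency bootstrap, and population false-positive rate.

An electrode is *conflict selective* (per alignment) when

1. the per-bin two-group F statistic comparing congruent vs incongruent
   raw power exceeds a permutation-derived significance threshold for at
   least 50 consecutive milliseconds (5 bins at the 10 ms hop), and
2. the across-trial mean baseline-z-scored power exceeds 1 at least once
   during the trial.

The per-bin threshold is the pointwise (1 - alpha) quantile of that
bin's label-permutation null, realised as the k-th largest permuted F
with k = max(1, floor(alpha * (n_perm + 1))), so the exceedance
probability under exchangeability is k/(n_perm + 1) ~= alpha.  Latency
is the time of the first bin of the first qualifying run; its s.e.m.
comes from a within-class trial bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import PowerTensor, zscore_display

MIN_RUN_MS = 50.0
AMP_Z = 1.0

#: where the run-length rule is evaluated, per alignment: the same
#: windows the single-trial power scalars use (stimulus onset to +1 s;
#: the final second before the response).  The amplitude criterion
#: still looks at the whole epoch (at least once during the trial).
DETECT_WINDOWS = {"stimulus": (0.0, 1.0), "response": (-1.0, 0.0)}


def detection_mask(times: np.ndarray, alignment: str,
                   window: tuple[float, float] | None = None) -> np.ndarray:
    """Boolean mask of bins where the run rule is evaluated."""
    if window is None:
        window = DETECT_WINDOWS.get(alignment)
    if window is None:
        return np.ones(times.size, bool)
    return (times >= window[0]) & (times <= window[1])


class SelectivityError(ValueError):
    pass


@dataclass
class SelectivityResult:
    electrode: int
    alignment: str
    f_trace: np.ndarray
    threshold: np.ndarray
    times: np.ndarray
    selective: bool
    amplitude_ok: bool
    latency: float | None           # s relative to the alignment event
    latency_sem: float | None
    n_perm: int
    pre_response: bool | None = None  # latency < 0 (response alignment only)


# ---------------------------------------------------------------------------
# F statistics, vectorized over label sets
# ---------------------------------------------------------------------------

def _f_two_group(power: np.ndarray, labelmat: np.ndarray) -> np.ndarray:
    """Two-group one-way F per bin for each row of ``labelmat``.

    power: (n_trials, n_bins); labelmat: (R, n_trials) boolean (True =
    incongruent).  Returns (R, n_bins).  Computed from group sums so the
    whole permutation family is two matrix products.
    """
    dtype = power.dtype if power.dtype in (np.float32, np.float64) \
        else np.float64
    p = np.ascontiguousarray(power, dtype=dtype)
    lm = np.ascontiguousarray(labelmat, dtype=dtype)
    n = p.shape[0]
    n1 = lm.sum(axis=1)
    n2 = n - n1
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise SelectivityError("each congruency class needs >= 2 trials")
    tot = p.sum(axis=0)                       # (bins,)
    ss_tot = (p * p).sum(axis=0) - tot ** 2 / n
    s1 = lm @ p                               # (R, bins)
    gm = tot / n
    m1 = s1 / n1[:, None]
    m2 = (tot[None, :] - s1) / n2[:, None]
    ssb = (n1[:, None] * (m1 - gm) ** 2 + n2[:, None] * (m2 - gm) ** 2)
    ssw = np.maximum(ss_tot[None, :] - ssb, 1e-30)
    return (ssb / ssw) * (n - 2)


def sliding_f(t: PowerTensor | np.ndarray, labels: np.ndarray,
              electrode: int = 0) -> np.ndarray:
    """Per-bin two-group F comparing incongruent vs congruent raw power."""
    power = t.power[electrode] if isinstance(t, PowerTensor) else np.asarray(t)
    labels = np.asarray(labels, bool)
    if labels.size != power.shape[0]:
        raise SelectivityError("labels length must match trial count")
    return _f_two_group(power, labels[None, :])[0].astype(float)


def _permuted_labels(labels: np.ndarray, n_perm: int,
                     rng: np.random.Generator) -> np.ndarray:
    lm = np.tile(np.asarray(labels, bool), (n_perm, 1))
    return rng.permuted(lm, axis=1)


def permutation_threshold(t: PowerTensor | np.ndarray, labels: np.ndarray,
                          alpha: float = 0.001, n_perm: int = 1000,
                          rng=None, electrode: int = 0) -> np.ndarray:
    """Pointwise per-bin F threshold from the label-permutation null.

    The smallest attainable level is 1/(n_perm + 1); requesting a smaller
    ``alpha`` silently uses the maximum permuted F (meaningful levels
    need n_perm >= 1/alpha).
    """
    if n_perm < 100:
        raise SelectivityError("n_perm < 100 gives meaningless thresholds")
    power = t.power[electrode] if isinstance(t, PowerTensor) else np.asarray(t)
    rng = np.random.default_rng(rng)
    lm = _permuted_labels(labels, n_perm, rng)
    f_perm = _f_two_group(power, lm)
    k = max(1, int(np.floor(alpha * (n_perm + 1))))
    # k-th largest per bin
    part = np.partition(f_perm, n_perm - k, axis=0)
    return part[n_perm - k].astype(float)


# ---------------------------------------------------------------------------
# run-length detection
# ---------------------------------------------------------------------------

def _min_run_bins(hop: float, min_run_ms: float = MIN_RUN_MS) -> int:
    return max(1, int(round(min_run_ms / 1000.0 / hop)))


def _first_run_start(above: np.ndarray, min_run: int) -> int:
    """Index of the first bin of the first run of >= min_run True, or -1."""
    if above.ndim != 1:
        raise SelectivityError("expected 1-D exceedance mask")
    a = above.astype(np.int8)
    c = np.convolve(a, np.ones(min_run, dtype=np.int8), mode="valid")
    hits = np.flatnonzero(c == min_run)
    return int(hits[0]) if hits.size else -1


def _runs_any(above: np.ndarray, min_run: int) -> np.ndarray:
    """Row-wise: does any run of >= min_run consecutive True exist?

    above: (R, n_bins) boolean.
    """
    a = above.astype(np.float32)
    c = np.cumsum(a, axis=1)
    c = np.concatenate([np.zeros((a.shape[0], 1), np.float32), c], axis=1)
    sums = c[:, min_run:] - c[:, :-min_run]
    return (sums >= min_run - 0.5).any(axis=1)


def amplitude_criterion(t: PowerTensor, electrode: int = 0,
                        z_thresh: float = AMP_Z) -> bool:
    """Across-all-trials mean z-scored power exceeds ``z_thresh`` somewhere."""
    z = zscore_display(t)
    return bool(z.power[electrode].mean(axis=0).max() > z_thresh)


def detect(t: PowerTensor, f_trace: np.ndarray, threshold: np.ndarray,
           electrode: int = 0, min_run_ms: float = MIN_RUN_MS,
           n_perm: int = 0,
           window: tuple[float, float] | None = None) -> SelectivityResult:
    """Apply the run-length and amplitude criteria to one electrode."""
    f_trace = np.asarray(f_trace, float)
    threshold = np.asarray(threshold, float)
    if f_trace.shape != threshold.shape or f_trace.size != t.times.size:
        raise SelectivityError("f_trace/threshold/time axis length mismatch")
    min_run = _min_run_bins(t.hop, min_run_ms)
    amp_ok = amplitude_criterion(t, electrode)
    mask = detection_mask(t.times, t.alignment, window)
    above = (f_trace > threshold) & mask
    start = _first_run_start(above, min_run)
    has_run = start >= 0
    selective = has_run and amp_ok
    latency = float(t.times[start]) if selective else None
    pre = (latency is not None and latency < 0) \
        if t.alignment == "response" else None
    return SelectivityResult(
        electrode=electrode, alignment=t.alignment, f_trace=f_trace,
        threshold=threshold, times=t.times, selective=selective,
        amplitude_ok=amp_ok, latency=latency, latency_sem=None,
        n_perm=n_perm, pre_response=pre)


def select_electrode(t: PowerTensor, labels: np.ndarray, electrode: int = 0,
                     alpha: float = 0.001, n_perm: int = 1000,
                     rng=None, min_run_ms: float = MIN_RUN_MS,
                     window: tuple[float, float] | None = None
                     ) -> SelectivityResult:
    """Threshold + detect for one electrode and alignment."""
    f = sliding_f(t, labels, electrode)
    thr = permutation_threshold(t, labels, alpha, n_perm, rng, electrode)
    return detect(t, f, thr, electrode, min_run_ms, n_perm, window)


def latency_bootstrap(t: PowerTensor, labels: np.ndarray,
                      threshold: np.ndarray, electrode: int = 0,
                      n_boot: int = 1000, rng=None,
                      min_run_ms: float = MIN_RUN_MS):
    """Trial-bootstrap mean and s.e.m. of the detection latency.

    Trials are resampled with replacement within each congruency class;
    the permutation threshold is held fixed (it is a property of the
    full dataset).  Replicates in which the electrode is no longer
    selective are dropped and their fraction reported; the latency is
    flagged unstable when fewer than half the replicates keep a
    qualifying run.
    """
    if n_boot < 2:
        raise SelectivityError("n_boot must be >= 2")
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels, bool)
    power = t.power[electrode]
    min_run = _min_run_bins(t.hop, min_run_ms)
    idx_i = np.flatnonzero(labels)
    idx_c = np.flatnonzero(~labels)
    mask = detection_mask(t.times, t.alignment)
    lats = []
    for _ in range(n_boot):
        bi = rng.choice(idx_i, idx_i.size, replace=True)
        bc = rng.choice(idx_c, idx_c.size, replace=True)
        sel = np.concatenate([bi, bc])
        lab = np.concatenate([np.ones(bi.size, bool),
                              np.zeros(bc.size, bool)])
        f = _f_two_group(power[sel], lab[None, :])[0]
        start = _first_run_start((f > threshold) & mask, min_run)
        if start >= 0:
            lats.append(t.times[start])
    frac_lost = 1.0 - len(lats) / n_boot
    if not lats:
        return np.nan, np.nan, frac_lost
    lats = np.asarray(lats)
    sem = lats.std(ddof=1) / np.sqrt(lats.size) if lats.size > 1 else 0.0
    return float(lats.mean()), float(sem), float(frac_lost)


# ---------------------------------------------------------------------------
# population false-positive rate and region enrichment
# ---------------------------------------------------------------------------

def _electrode_fp_matrix(power: np.ndarray, labels: np.ndarray,
                         amp_ok: bool, n_shuffles: int, alpha: float,
                         n_perm: int, min_run: int, rng,
                         reuse_thresholds: bool,
                         mask: np.ndarray | None = None) -> np.ndarray:
    """(n_shuffles,) boolean: did this electrode pass under each shuffle."""
    if not amp_ok:
        return np.zeros(n_shuffles, bool)
    if mask is None:
        mask = np.ones(power.shape[1], bool)
    k = max(1, int(np.floor(alpha * (n_perm + 1))))
    obs_lm = _permuted_labels(labels, n_shuffles, rng)
    f_obs = _f_two_group(power, obs_lm)
    if reuse_thresholds:
        lm = _permuted_labels(labels, n_perm, rng)
        f_perm = _f_two_group(power, lm)
        thr = np.partition(f_perm, n_perm - k, axis=0)[n_perm - k]
        return _runs_any((f_obs > thr[None, :]) & mask[None, :], min_run)
    out = np.zeros(n_shuffles, bool)
    for r in range(n_shuffles):
        lm = _permuted_labels(labels, n_perm, rng)
        f_perm = _f_two_group(power, lm)
        thr = np.partition(f_perm, n_perm - k, axis=0)[n_perm - k]
        out[r] = _runs_any(((f_obs[r] > thr) & mask)[None, :], min_run)[0]
    return out


def estimate_false_positives(tensor_pairs, labels_per_subject,
                             n_shuffles: int = 100, alpha: float = 0.001,
                             n_perm: int = 1000, rng=None,
                             min_run_ms: float = MIN_RUN_MS,
                             reuse_thresholds: bool = False):
    """Mean count of electrodes passing the full selection under label
    shuffles (the empirical false-discovery calibration of the detector).

    Parameters
    ----------
    tensor_pairs : list of (PowerTensor | None, ...) tuples
        One tuple per subject with that subject's tensors for each
        alignment (typically ``(stimulus, response)``); an electrode
        passes a shuffle replicate when it passes in *any* alignment.
    labels_per_subject : list of boolean arrays (True = incongruent),
        one per subject per alignment tensor (same trial subset).
    reuse_thresholds : compute the per-bin permutation threshold once per
        electrode and share it across shuffle replicates.  Each shuffled
        labeling is exchangeable with the threshold permutations, so the
        mean count is unbiased; only the across-replicate s.e.m. becomes
        approximate.  Default False (faithful recompute per replicate).

    Returns ``(mean_count, sem, q, fired)`` where ``q`` = mean count /
    population size and ``fired`` is the (n_electrodes_total, n_shuffles)
    boolean pass matrix (for region-level chance distributions).
    """
    if n_shuffles < 10:
        raise SelectivityError("n_shuffles must be >= 10")
    rng = np.random.default_rng(rng)
    fired_rows = []
    for tensors, labels in zip(tensor_pairs, labels_per_subject):
        tensors = [tt for tt in tensors if tt is not None]
        if not isinstance(labels, (list, tuple)):
            labels = [labels] * len(tensors)
        n_elec = tensors[0].n_electrodes
        min_runs = [_min_run_bins(tt.hop, min_run_ms) for tt in tensors]
        masks = [detection_mask(tt.times, tt.alignment) for tt in tensors]
        for e in range(n_elec):
            passed = np.zeros(n_shuffles, bool)
            for tt, lab, mr, mk in zip(tensors, labels, min_runs, masks):
                amp_ok = amplitude_criterion(tt, e)
                passed |= _electrode_fp_matrix(
                    tt.power[e], np.asarray(lab, bool), amp_ok, n_shuffles,
                    alpha, n_perm, mr, rng, reuse_thresholds, mk)
            fired_rows.append(passed)
    if len(fired_rows) < 2:
        raise SelectivityError("population needs >= 2 electrodes")
    fired = np.vstack(fired_rows)
    counts = fired.sum(axis=0)
    mean = float(counts.mean())
    sem = float(counts.std(ddof=1) / np.sqrt(n_shuffles))
    return mean, sem, mean / fired.shape[0], fired


def region_enrichment(selective: np.ndarray, regions: np.ndarray,
                      fired: np.ndarray) -> pd.DataFrame:
    """Per-region p for the observed selective count vs shuffle chance.

    ``fired`` is the pass matrix from ``estimate_false_positives`` (rows
    in the same electrode order).  p = fraction of shuffle replicates
    whose region count is >= the observed count (add-one corrected).
    """
    selective = np.asarray(selective, bool)
    regions = np.asarray(regions)
    rows = []
    n_shuffles = fired.shape[1]
    for region in pd.unique(regions):
        m = regions == region
        if m.sum() == 0:
            continue
        obs = int(selective[m].sum())
        null_counts = fired[m].sum(axis=0)
        p = (1 + int((null_counts >= obs).sum())) / (n_shuffles + 1)
        rows.append(dict(region=region, n_electrodes=int(m.sum()),
                         n_selective=obs, chance_mean=float(null_counts.mean()),
                         p=p))
    return pd.DataFrame(rows)
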