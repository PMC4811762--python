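"""Single-electrode analyses: RT correlations, Congruency x Task
interaction, the neural Gratton effect with its two confound controls,
and error-monitoring contrasts.

The per-trial scalar is the maximal (or mean) band power inside the
analysis window — stimulus-aligned [0, +1] s or response-aligned
[-1, 0] s.  All statistics run on raw (linear) power.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .preprocess import PowerTensor, zscore_display

STIM_WINDOW = (0.0, 1.0)
RESP_WINDOW = (-1.0, 0.0)


class TrialStatsError(ValueError):
    pass


@dataclass
class TrialScalars:
    values: np.ndarray      # (n_trials,) per-trial power scalar
    peak_times: np.ndarray  # time of maximal power, s rel alignment event
    window: tuple
    mode: str
    electrode: int
    trial_index: np.ndarray


def single_trial_power(t: PowerTensor, electrode: int = 0,
                       mode: str = "max",
                       window: tuple[float, float] | None = None
                       ) -> TrialScalars:
    """Per-trial power scalar (max or mean over the analysis window)."""
    if mode not in ("max", "mean"):
        raise TrialStatsError(f"unknown mode {mode!r}")
    if window is None:
        window = RESP_WINDOW if t.alignment == "response" else STIM_WINDOW
    sel = (t.times >= window[0]) & (t.times <= window[1])
    if not sel.any():
        raise TrialStatsError("analysis window outside tensor time axis")
    p = t.power[electrode][:, sel]
    vals = p.max(axis=1) if mode == "max" else p.mean(axis=1)
    peaks = t.times[sel][p.argmax(axis=1)]
    return TrialScalars(values=vals.astype(float), peak_times=peaks,
                        window=window, mode=mode, electrode=electrode,
                        trial_index=t.trial_index)


def power_rt_correlation(values: np.ndarray, rts: np.ndarray,
                         n_perm: int = 1000, rng=None):
    """Pearson r between per-trial power and RT, permutation p.

    The permutation null shuffles the RT pairing; p is the add-one
    corrected fraction of |r_perm| >= |r| (two-sided).
    """
    v = np.asarray(values, float)
    r_t = np.asarray(rts, float)
    ok = np.isfinite(v) & np.isfinite(r_t)
    v, r_t = v[ok], r_t[ok]
    if v.size < 10:
        raise TrialStatsError("need >= 10 trials for the correlation")
    if v.std() == 0 or r_t.std() == 0:
        raise TrialStatsError("zero variance in power or RT")
    r = float(scipy.stats.pearsonr(v, r_t).statistic)
    rng = np.random.default_rng(rng)
    vz = (v - v.mean()) / v.std()
    rz = (r_t - r_t.mean()) / r_t.std()
    perms = np.empty(n_perm)
    for i in range(n_perm):
        perms[i] = vz @ rng.permutation(rz) / v.size
    p = (1 + int((np.abs(perms) >= abs(r)).sum())) / (n_perm + 1)
    return r, p


# ---------------------------------------------------------------------------
# Congruency x Task interaction
# ---------------------------------------------------------------------------

def _interaction_f_bins(power: np.ndarray, cong: np.ndarray,
                        task: np.ndarray) -> np.ndarray:
    """Two-way factorial interaction F per bin (regression formulation).

    power: (n_trials, n_bins).  F = ((SSE_red - SSE_full)/1) /
    (SSE_full/(n-4)), full model = intercept + C + T + C:T.
    """
    n = power.shape[0]
    c = np.asarray(cong, float)
    t = np.asarray(task, float)
    x_full = np.column_stack([np.ones(n), c, t, c * t])
    x_red = x_full[:, :3]
    q_full, _ = np.linalg.qr(x_full)
    q_red, _ = np.linalg.qr(x_red)
    p = np.asarray(power, float)
    tot = (p * p).sum(axis=0)
    proj_full = (q_full.T @ p)
    proj_red = (q_red.T @ p)
    sse_full = np.maximum(tot - (proj_full ** 2).sum(axis=0), 1e-30)
    sse_red = tot - (proj_red ** 2).sum(axis=0)
    return ((sse_red - sse_full) / (sse_full / (n - 4)))


def interaction_peak_f(power: np.ndarray, cong: np.ndarray,
                       task: np.ndarray, times: np.ndarray,
                       pre_window: tuple[float, float] = RESP_WINDOW,
                       n_perm: int = 1000, rng=None):
    """Peak Congruency x Task interaction F over the pre-response window.

    ``power`` is (n_trials, n_bins) pooling both tasks' response-aligned
    trials.  p comes from jointly shuffling the 4-level cell label
    across trials (preserving marginal cell counts) and recomputing the
    peak F.
    """
    cong = np.asarray(cong, bool)
    task = np.asarray(task, bool)
    counts = [(c & t).sum() for c in (cong, ~cong) for t in (task, ~task)]
    if min(counts) == 0:
        raise TrialStatsError("all four Congruency x Task cells must be "
                              "non-empty")
    sel = (times >= pre_window[0]) & (times <= pre_window[1])
    if not sel.any():
        raise TrialStatsError("empty pre-response window")
    p = np.asarray(power, float)[:, sel]
    obs = float(_interaction_f_bins(p, cong, task).max())
    rng = np.random.default_rng(rng)
    n = p.shape[0]
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        null[i] = _interaction_f_bins(p, cong[perm], task[perm]).max()
    pval = (1 + int((null >= obs).sum())) / (n_perm + 1)
    return obs, pval


# ---------------------------------------------------------------------------
# neural Gratton effect + confound controls
# ---------------------------------------------------------------------------

def gratton_contrast(values: np.ndarray, history: np.ndarray,
                     pair: tuple[str, str] = ("cI", "iI")):
    """Raw mean power difference between two history classes."""
    v = np.asarray(values, float)
    h = np.asarray(history)
    a, b = pair
    return float(v[h == a].mean() - v[h == b].mean())


def gratton_ancova(values: np.ndarray, history: np.ndarray,
                   rts: np.ndarray, pair: tuple[str, str] = ("cI", "iI"),
                   min_per_cell: int = 5):
    """RT-adjusted history contrast via common-slope ANCOVA.

    Fits power ~ history + RT (common slope) on the two history classes
    and returns the intercept difference (first minus second class),
    i.e. the contrast at any fixed RT, with its t-test p.  Stimulus-
    repeat trials must already be removed.
    """
    v = np.asarray(values, float)
    h = np.asarray(history)
    r = np.asarray(rts, float)
    sel = np.isin(h, pair) & np.isfinite(r) & np.isfinite(v)
    v, h, r = v[sel], h[sel], r[sel]
    na, nb = (h == pair[0]).sum(), (h == pair[1]).sum()
    if na < min_per_cell or nb < min_per_cell:
        raise TrialStatsError(f"need >= {min_per_cell} trials per history "
                              f"cell (got {na}, {nb})")
    if r.std() == 0:
        raise TrialStatsError("degenerate RT spread")
    g = (h == pair[0]).astype(float)
    x = np.column_stack([np.ones(v.size), g, r - r.mean()])
    coef, _, rank, _ = np.linalg.lstsq(x, v, rcond=None)
    if rank < 3:
        raise TrialStatsError("collinear ANCOVA design")
    resid = v - x @ coef
    dof = v.size - 3
    s2 = resid @ resid / dof
    cov = s2 * np.linalg.inv(x.T @ x)
    tstat = coef[1] / np.sqrt(cov[1, 1])
    p = 2 * scipy.stats.t.sf(abs(tstat), dof)
    return float(coef[1]), float(p)


def rt_matched_subsample(values: np.ndarray, history: np.ndarray,
                         rts: np.ndarray,
                         pair: tuple[str, str] = ("cI", "iI"),
                         bin_s: float = 0.2, rng=None):
    """Histogram-matched history contrast (RT equalised by subsampling).

    Within each 200 ms RT bin both history classes are subsampled to the
    smaller count.  Returns (contrast, retention_fraction, kept_index).
    """
    rng = np.random.default_rng(rng)
    v = np.asarray(values, float)
    h = np.asarray(history)
    r = np.asarray(rts, float)
    sel = np.isin(h, pair) & np.isfinite(r) & np.isfinite(v)
    idx = np.flatnonzero(sel)
    if idx.size == 0:
        raise TrialStatsError("no trials in the requested history classes")
    bins = np.floor(r[idx] / bin_s).astype(int)
    keep = []
    for b in np.unique(bins):
        ia = idx[(bins == b) & (h[idx] == pair[0])]
        ib = idx[(bins == b) & (h[idx] == pair[1])]
        m = min(ia.size, ib.size)
        if m == 0:
            continue
        keep.extend(rng.choice(ia, m, replace=False))
        keep.extend(rng.choice(ib, m, replace=False))
    if not keep:
        raise TrialStatsError("no overlapping RT bins between classes")
    keep = np.asarray(sorted(keep))
    contrast = gratton_contrast(v[keep], h[keep], pair)
    return contrast, keep.size / idx.size, keep


# ---------------------------------------------------------------------------
# error monitoring
# ---------------------------------------------------------------------------

def error_monitoring(post_error: np.ndarray, post_corrected: np.ndarray,
                     min_trials: int = 5):
    """Paired error-vs-correction contrast in the 1 s post-response window.

    Inputs are per-trial mean z-scored power after the erroneous and the
    corrected response onsets (same self-correction trials).  Returns
    (mean difference, signed-rank p) or None when fewer than
    ``min_trials`` trials are available (electrode skipped).
    """
    a = np.asarray(post_error, float)
    b = np.asarray(post_corrected, float)
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if a.size < min_trials:
        return None
    diff = a - b
    mode = "exact" if a.size <= 25 else "approx"
    res = scipy.stats.wilcoxon(diff, alternative="greater", method=mode)
    return float(diff.mean()), float(res.pvalue)


def post_response_zpower(t: PowerTensor, electrode: int = 0,
                         window: tuple[float, float] = (0.0, 1.0)
                         ) -> np.ndarray:
    """Per-trial mean z-scored power in the post-response window."""
    z = zscore_display(t)
    sel = (t.times >= window[0]) & (t.times <= window[1])
    if not sel.any():
        raise TrialStatsError("post-response window outside tensor")
    return z.power[electrode][:, sel].mean(axis=1)
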