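"""Theta-phase -> gamma-amplitude coupling via the Modulation Index.

Band signals come from zero-phase least-squares FIR filters (phase from
the analytic signal of the low band, amplitude from the high band).  The
Modulation Index is the normalised Kullback-Leibler divergence between
the phase-binned amplitude distribution and the uniform distribution:

    MI = (log N - H(P)) / log N,  P_j = <A>_j / sum_k <A>_k

over N phase bins (default 18, i.e. 20 deg).  Significance comes from
surrogates that circularly lag the amplitude series against the phase
series; condition differences equalise trial counts and permute labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.signal

THETA = (4.0, 8.0)
HIGH_GAMMA = (70.0, 120.0)
N_BINS = 18


class CFCError(ValueError):
    pass


@dataclass
class PACResult:
    mi: float
    phase_bins: np.ndarray          # bin centers, radians in (-pi, pi)
    amp_means: np.ndarray           # mean amplitude per phase bin
    surrogate_mis: np.ndarray | None
    p: float | None
    n_trials: int | None = None


def design_fir(band: tuple[float, float], fs: float,
               cycles: float = 3.0, transition: float = 0.2) -> np.ndarray:
    """Least-squares linear-phase FIR band-pass (odd length).

    Filter order spans ``cycles`` periods of the band's low edge;
    transition bands are ``transition`` x the corresponding edge.
    """
    lo, hi = band
    n = int(round(cycles * fs / lo))
    n += (n + 1) % 2  # odd length -> type-I linear phase
    t_lo, t_hi = transition * lo, transition * hi
    nyq = fs / 2
    if hi + t_hi >= nyq:
        raise CFCError(f"band {band} too close to Nyquist {nyq}")
    bands = [0, lo - t_lo, lo, hi, hi + t_hi, nyq]
    desired = [0, 0, 1, 1, 0, 0]
    return scipy.signal.firls(n, bands, desired, fs=fs)


def _zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    return scipy.signal.filtfilt(taps, [1.0], x)


def phase_amplitude(signal: np.ndarray, fs: float,
                    low: tuple[float, float] = THETA,
                    high: tuple[float, float] = HIGH_GAMMA):
    """Instantaneous low-band phase and high-band amplitude (Hilbert)."""
    x = np.asarray(signal, float)
    min_len = int(3 * fs / low[0])
    if x.size < min_len:
        raise CFCError(f"signal shorter than 3 cycles of {low[0]} Hz")
    lo_taps = design_fir(low, fs)
    hi_taps = design_fir(high, fs)
    xl = _zero_phase(x, lo_taps)
    xh = _zero_phase(x, hi_taps)
    phase = np.angle(scipy.signal.hilbert(xl))
    amp = np.abs(scipy.signal.hilbert(xh))
    return phase, amp


def modulation_index(phase: np.ndarray, amp: np.ndarray,
                     n_bins: int = N_BINS) -> PACResult:
    """Tort-style MI from phase-binned mean amplitudes.

    Empty phase bins are merged into their neighbour (with a warning via
    the returned histogram having fewer effective bins is avoided by
    assigning the neighbour's mean); with >= 10 samples per bin on
    average this never triggers on real traces.
    """
    phase = np.asarray(phase, float)
    amp = np.asarray(amp, float)
    if phase.shape != amp.shape:
        raise CFCError("phase and amplitude must have equal length")
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    which = np.clip(np.digitize(phase, edges) - 1, 0, n_bins - 1)
    sums = np.bincount(which, weights=amp, minlength=n_bins)
    counts = np.bincount(which, minlength=n_bins)
    means = np.full(n_bins, np.nan)
    nz = counts > 0
    means[nz] = sums[nz] / counts[nz]
    if not nz.all():  # merge-adjacent fallback for empty bins
        idx = np.flatnonzero(nz)
        for j in np.flatnonzero(~nz):
            means[j] = means[idx[np.argmin(np.abs(idx - j))]]
    p = means / means.sum()
    h = -np.sum(p[p > 0] * np.log(p[p > 0]))
    mi = (np.log(n_bins) - h) / np.log(n_bins)
    centers = (edges[:-1] + edges[1:]) / 2
    return PACResult(mi=float(mi), phase_bins=centers, amp_means=means,
                     surrogate_mis=None, p=None)


def mi_surrogate_test(phase: np.ndarray, amp: np.ndarray, fs: float,
                      n_surr: int = 1000, rng=None,
                      n_bins: int = N_BINS,
                      min_lag_s: float = 1.0) -> PACResult:
    """Lag-surrogate test of the MI.

    Each surrogate circularly shifts the amplitude series by a lag drawn
    uniformly from [min_lag_s, T - min_lag_s] (avoiding trivially small
    offsets) and recomputes the MI; p = (1 + #{surr >= obs})/(n_surr+1).
    """
    if n_surr < 100:
        raise CFCError("n_surr must be >= 100")
    rng = np.random.default_rng(rng)
    obs = modulation_index(phase, amp, n_bins)
    n = len(amp)
    min_lag = int(min_lag_s * fs)
    if 2 * min_lag >= n:
        min_lag = max(1, n // 4)
    lags = rng.integers(min_lag, n - min_lag, size=n_surr)
    surr = np.empty(n_surr)
    for i, lag in enumerate(lags):
        surr[i] = modulation_index(phase, np.roll(amp, lag), n_bins).mi
    p = (1 + int((surr >= obs.mi).sum())) / (n_surr + 1)
    return PACResult(mi=obs.mi, phase_bins=obs.phase_bins,
                     amp_means=obs.amp_means, surrogate_mis=surr, p=p)


def trial_swap_surrogate_test(phases: list, amps: list, n_surr: int = 1000,
                              rng=None, n_bins: int = N_BINS) -> PACResult:
    """Alternative surrogate: pair phase and amplitude from different
    trials (cyclic trial shift), preserving within-trial structure."""
    if n_surr < 100:
        raise CFCError("n_surr must be >= 100")
    rng = np.random.default_rng(rng)
    obs = modulation_index(np.concatenate(phases), np.concatenate(amps),
                           n_bins)
    n_tr = len(phases)
    surr = np.empty(n_surr)
    for i in range(n_surr):
        shift = rng.integers(1, n_tr)
        a = [amps[(j + shift) % n_tr][:len(phases[j])] for j in range(n_tr)]
        ph = [phases[j][:len(a[j])] for j in range(n_tr)]
        surr[i] = modulation_index(np.concatenate(ph), np.concatenate(a),
                                   n_bins).mi
    p = (1 + int((surr >= obs.mi).sum())) / (n_surr + 1)
    return PACResult(mi=obs.mi, phase_bins=obs.phase_bins,
                     amp_means=obs.amp_means, surrogate_mis=surr, p=p)


def mean_vector_length(phase: np.ndarray, amp: np.ndarray) -> float:
    """Canolty-style coupling estimator |mean(A e^{i phi})| / mean(A),
    used as an independent cross-check of the MI's rank ordering."""
    amp = np.asarray(amp, float)
    return float(np.abs(np.mean(amp * np.exp(1j * np.asarray(phase)))) /
                 amp.mean())


def _concat_mi(phases, amps, idx, n_bins):
    ph = np.concatenate([phases[i] for i in idx])
    am = np.concatenate([amps[i] for i in idx])
    return modulation_index(ph, am, n_bins).mi


def mi_condition_difference(phases_c: list, amps_c: list, phases_i: list,
                            amps_i: list, n_perm: int = 1000, rng=None,
                            n_bins: int = N_BINS):
    """MI difference between conditions with equalised trial counts.

    The larger condition is subsampled (seeded) to the smaller's count;
    delta = MI(I) - MI(C).  p is two-sided from shuffling the condition
    labels over the pooled, equalised trials.
    """
    rng = np.random.default_rng(rng)
    n_c, n_i = len(phases_c), len(phases_i)
    if min(n_c, n_i) < 10:
        raise CFCError("need >= 10 trials per condition")
    m = min(n_c, n_i)
    keep_c = np.sort(rng.choice(n_c, m, replace=False))
    keep_i = np.sort(rng.choice(n_i, m, replace=False))
    ph = [phases_c[i] for i in keep_c] + [phases_i[i] for i in keep_i]
    am = [amps_c[i] for i in keep_c] + [amps_i[i] for i in keep_i]
    idx_c = np.arange(m)
    idx_i = np.arange(m, 2 * m)
    delta = _concat_mi(ph, am, idx_i, n_bins) - _concat_mi(ph, am, idx_c,
                                                           n_bins)
    null = np.empty(n_perm)
    for it in range(n_perm):
        perm = rng.permutation(2 * m)
        null[it] = (_concat_mi(ph, am, perm[m:], n_bins) -
                    _concat_mi(ph, am, perm[:m], n_bins))
    p = (1 + int((np.abs(null) >= abs(delta)).sum())) / (n_perm + 1)
    return float(delta), float(p)
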