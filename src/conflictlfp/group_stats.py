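"""Population-level inference with electrodes nested in subjects.

Fixed effects of interest (e.g. Congruency x Task, history x task) are
tested with a likelihood-ratio test between maximum-likelihood mixed
models that differ only in the tested term; random intercepts are
subject and electrode-within-subject.  Statistical tests consume raw
power; incongruent/congruent log-ratios are computed for display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .preprocess import PowerTensor


class GroupStatsError(ValueError):
    pass


@dataclass
class GroupTestResult:
    formula_full: str
    formula_null: str
    tested_term: str
    chi2: float
    df: int
    p: float
    fitted_means: pd.DataFrame | None
    fallback: str | None = None     # set when the mixed fit degenerated


def _fit_ml(formula: str, data: pd.DataFrame, vc: dict | None):
    """ML fit, robust to optimizer-dependent local optima.

    A likelihood-ratio test needs both models near their global ML
    optimum; a single optimizer occasionally parks one model's variance
    component at a poor local solution, which corrupts the LRT.  Each
    model is therefore fit with two optimizers and the better
    likelihood kept.
    """
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, data, groups=data["subject"],
                            vc_formula=vc)
        for method in ("lbfgs", "bfgs"):
            try:
                res = model.fit(reml=False, method=method, maxiter=200)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(res.llf) and (best is None or
                                         res.llf > best.llf):
                best = res
    if best is None:
        raise np.linalg.LinAlgError("mixed model fit failed")
    return best


def multilevel_test(data: pd.DataFrame, outcome: str, full_rhs: str,
                    null_rhs: str, tested_term: str | None = None
                    ) -> GroupTestResult:
    """Likelihood-ratio test of a fixed term in a nested mixed model.

    ``data`` needs ``subject`` and ``electrode`` columns plus the
    outcome and factors.  Random structure: intercept per subject and
    per electrode-within-subject, ML estimation.  On a singular or
    non-converged fit the test falls back to subject-level aggregation
    (an OLS LRT on per-subject-condition means) with a warning recorded
    in ``fallback``.
    """
    for col in ("subject", "electrode", outcome):
        if col not in data.columns:
            raise GroupStatsError(f"missing column {col!r}")
    if data["subject"].nunique() < 2:
        raise GroupStatsError("need >= 2 subjects")
    d = data.copy()
    d["subject"] = d["subject"].astype(str)
    d["electrode"] = d["electrode"].astype(str)
    vc = {"electrode": "0 + C(electrode)"}
    f_full = f"{outcome} ~ {full_rhs}"
    f_null = f"{outcome} ~ {null_rhs}"
    term = tested_term or full_rhs
    fallback = None
    try:
        m_full = _fit_ml(f_full, d, vc)
        m_null = _fit_ml(f_null, d, vc)
        if not (np.isfinite(m_full.llf) and np.isfinite(m_null.llf)):
            raise np.linalg.LinAlgError("non-finite likelihood")
        chi2 = 2.0 * (m_full.llf - m_null.llf)
        df = m_full.df_modelwc - m_null.df_modelwc
        fitted = _condition_means(d, outcome, full_rhs)
    except (np.linalg.LinAlgError, ValueError):
        fallback = "subject-aggregate OLS LRT (singular mixed fit)"
        agg_cols = sorted({c for c in _rhs_columns(full_rhs)
                           if c in d.columns})
        agg = (d.groupby(["subject"] + agg_cols)[outcome]
               .mean().reset_index())
        m_full = smf.ols(f_full, agg).fit()
        m_null = smf.ols(f_null, agg).fit()
        chi2 = 2.0 * (m_full.llf - m_null.llf)
        df = int(m_full.df_model - m_null.df_model)
        fitted = _condition_means(agg, outcome, full_rhs)
    df = max(int(round(df)), 1)
    chi2 = max(float(chi2), 0.0)
    p = float(scipy.stats.chi2.sf(chi2, df))
    return GroupTestResult(formula_full=f_full, formula_null=f_null,
                           tested_term=term, chi2=chi2, df=df, p=p,
                           fitted_means=fitted, fallback=fallback)


def _rhs_columns(rhs: str) -> list[str]:
    import re
    toks = re.split(r"[+*:()\s]", rhs)
    return [t for t in toks if t and not t.replace(".", "").isdigit()
            and t not in ("C", "1", "0")]


def _condition_means(d: pd.DataFrame, outcome: str, rhs: str):
    cols = [c for c in _rhs_columns(rhs) if c in d.columns]
    if not cols:
        return None
    return d.groupby(cols)[outcome].mean().reset_index()


def region_log_ratio(t: PowerTensor, labels: np.ndarray,
                     electrodes: np.ndarray) -> np.ndarray:
    """Average incongruent/congruent log-ratio trace over electrodes.

    Per electrode: bin-wise log(mean I power / mean C power); the
    returned trace is the across-electrode mean.  Display-only output.
    """
    labels = np.asarray(labels, bool)
    electrodes = np.atleast_1d(electrodes)
    if electrodes.size == 0:
        raise GroupStatsError("need >= 1 electrode")
    traces = []
    for e in electrodes:
        mi = t.power[e][labels].mean(axis=0)
        mc = t.power[e][~labels].mean(axis=0)
        if np.any(mi <= 0) or np.any(mc <= 0):
            raise GroupStatsError("non-positive mean power in a bin")
        traces.append(np.log(mi / mc))
    return np.mean(traces, axis=0)


def population_signrank(values: np.ndarray,
                        alternative: str = "two-sided") -> float:
    """One-sample signed-rank p of per-electrode statistics against 0."""
    v = np.asarray(values, float)
    v = v[np.isfinite(v)]
    if v.size < 6:
        raise GroupStatsError("need >= 6 electrodes")
    if np.all(v == 0):
        raise GroupStatsError("ties-only input")
    mode = "exact" if v.size <= 25 and not np.any(v == 0) else "approx"
    res = scipy.stats.wilcoxon(v, alternative=alternative, method=mode)
    return float(res.pvalue)
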