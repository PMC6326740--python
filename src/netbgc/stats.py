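"""Correlation inference, residualization, FDR and association tables.

All correlation tests use the t reference distribution: for an estimate r
(Pearson, or Spearman via average ranks) on n pairs,

    t = r * sqrt((n - 2) / (1 - r^2)),   p = 2 * P(T_{n-2} > |t|),

and partial correlations lose one further degree of freedom per covariate.
Two independent correlations are compared with the Fisher z transform,

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)).

This independent-samples formula is also applied when comparing two
connectivity-symptom correlations measured on the same subjects: the
dependent-correlation alternatives need the (usually unreported)
inter-measure correlation, and the independent form is the convention this
package follows for that comparison.  Multiple testing uses the
Benjamini-Hochberg step-up; each table (the networks, or the regions)
forms its own family and families are never pooled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CorrelationResult",
    "CorrelationComparison",
    "correlation_test",
    "p_from_correlation",
    "partial_rank_correlation",
    "residualize",
    "bh_fdr",
    "compare_correlations",
    "association_table",
]


@dataclass(frozen=True)
class CorrelationResult:
    method: str
    estimate: float
    n: int
    df: int
    statistic: float
    p: float
    p_fdr: float | None = None


@dataclass(frozen=True)
class CorrelationComparison:
    z: float
    p: float


def _t_pvalue(estimate: float, df: int) -> tuple[float, float]:
    if abs(estimate) >= 1.0:
        return float(np.sign(estimate) * np.inf), 0.0
    t = estimate * np.sqrt(df / (1.0 - estimate**2))
    return float(t), float(2.0 * sps.t.sf(abs(t), df))


def p_from_correlation(estimate: float, n: int, n_covariates: int = 0) -> float:
    """Two-tailed p for a correlation estimate at sample size n.

    Uses the t reference with n - 2 - n_covariates degrees of freedom; the
    same formula serves Pearson r and the t approximation for Spearman rho.
    """
    df = n - 2 - n_covariates
    if df < 1:
        raise ValueError("not enough degrees of freedom")
    return _t_pvalue(float(estimate), df)[1]


def _validate_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("missing or non-finite values")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    return x, y


def correlation_test(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson or Spearman correlation with a two-tailed t-based p-value."""
    x, y = _validate_pair(x, y)
    if method == "spearman":
        x = sps.rankdata(x)
        y = sps.rankdata(y)
    elif method != "pearson":
        raise ValueError("method must be 'pearson' or 'spearman'")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    t, p = _t_pvalue(r, df)
    return CorrelationResult(method, r, x.size, df, t, p)


def residualize(y, covariates) -> np.ndarray:
    """Least-squares residuals of y on an intercept plus the covariates."""
    y = np.asarray(y, dtype=float).ravel()
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != y.size:
        c = c.T
    if c.shape[0] != y.size:
        raise ValueError("covariates do not align with y")
    x = np.column_stack([np.ones(y.size), c])
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient covariate design")
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta


def partial_rank_correlation(x, y, covariates=None) -> CorrelationResult:
    """Rank-based partial correlation of x and y given covariates.

    All variables are rank-transformed (average ranks), x and y are
    residualized on the covariates plus an intercept, and the residuals are
    correlated; p uses n - 2 - k degrees of freedom.  With no covariates
    this reduces exactly to the Spearman correlation test.
    """
    x, y = _validate_pair(x, y)
    if covariates is None or (hasattr(covariates, "__len__") and len(covariates) == 0):
        return replace(correlation_test(x, y, "spearman"), method="partial_spearman")
    c = np.atleast_2d(np.asarray(covariates, dtype=float))
    if c.shape[0] != x.size:
        c = c.T
    if c.shape[0] != x.size:
        raise ValueError("covariates do not align with x and y")
    k = c.shape[1]
    n = x.size
    if n <= k + 3:
        raise ValueError("too few observations for the covariate count")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rc = np.column_stack([sps.rankdata(c[:, j]) for j in range(k)])
    ex = residualize(rx, rc)
    ey = residualize(ry, rc)
    if ex.std() < 1e-12 * rx.std() or ey.std() < 1e-12 * ry.std():
        r = 0.0
    else:
        r = float(np.corrcoef(ex, ey)[0, 1])
    df = n - 2 - k
    t, p = _t_pvalue(r, df)
    return CorrelationResult("partial_spearman", r, n, df, t, p)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up, capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("pvals must be a non-empty 1-D array")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_correlations(
    r1: float, n1: int, r2: float, n2: int
) -> CorrelationComparison:
    """Fisher z comparison of two correlation coefficients.

    Returns the signed z statistic and the two-tailed normal p-value.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("correlations must have magnitude < 1")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3 in each sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3)
    )
    p = float(2.0 * sps.norm.sf(abs(z)))
    return CorrelationComparison(float(z), p)


def association_table(
    measures: pd.DataFrame,
    symptom,
    method: str = "pearson",
    fdr: bool = True,
) -> pd.DataFrame:
    """Correlate each row of a unit x subject matrix with a symptom score.

    ``measures`` has one row per unit (network or region) and one column
    per subject, aligned with ``symptom``.  Returns a table with columns
    unit, estimate, p, p_fdr (BH across all units of this table when
    ``fdr`` is set), n and method.
    """
    if not isinstance(measures, pd.DataFrame):
        raise TypeError("measures must be a unit x subject DataFrame")
    symptom = np.asarray(symptom, dtype=float)
    if measures.shape[1] != symptom.size:
        raise ValueError("subject dimensions do not align")
    if symptom.size < 4:
        raise ValueError("need at least 4 subjects")
    rows = []
    for unit, series in measures.iterrows():
        res = correlation_test(series.to_numpy(), symptom, method)
        rows.append((unit, res.estimate, res.p, res.n))
    table = pd.DataFrame(rows, columns=["unit", "estimate", "p", "n"])
    table["p_fdr"] = bh_fdr(table["p"].to_numpy()) if fdr else np.nan
    table["method"] = method
    return table[["unit", "estimate", "p", "p_fdr", "n", "method"]]
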