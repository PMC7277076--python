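"""Reliability coefficients and validity / group-contrast statistics.

Internal consistency via Cronbach's alpha (and its dichotomous-item
specialization KR-20), criterion validity via product-moment correlations,
and group contrasts via the pooled-variance t test, the Mann-Whitney U
(both orientations, since the reporting convention varies), and the
chi-square test of independence.  The t test defaults to the pooled
(Student) form, matching degrees of freedom n1 + n2 - 2; Welch is
available behind a flag.  p-values come from the standard reference
distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ReliabilityReport",
    "cronbach_alpha",
    "kr20",
    "pearson_r",
    "two_sample_t",
    "mann_whitney_u",
    "chi_square_independence",
]


@dataclass
class ReliabilityReport:
    """Alpha per scale/subscale plus KR-20 for the binary reference."""

    alpha: dict[str, float]
    kr20: float | None = None


def _item_matrix(items) -> np.ndarray:
    x = np.asarray(getattr(items, "to_numpy", lambda: items)(), dtype=float)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a person x item matrix with >= 2 items")
    if x.shape[0] < 2:
        raise ValueError("need >= 2 persons")
    return x


def cronbach_alpha(items) -> float:
    """alpha = k/(k-1) * (1 - sum(item variances) / variance of the total).

    Sample (ddof=1) variances throughout.  Raises on zero total variance.
    """
    x = _item_matrix(items)
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance")
    item_var = x.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def kr20(items) -> float:
    """Kuder-Richardson 20 for dichotomous items: item variance p(1-p)."""
    x = _item_matrix(items)
    if not np.isin(x[~np.isnan(x)], [0, 1]).all():
        raise ValueError("KR-20 requires binary (0/1) items")
    k = x.shape[1]
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise ValueError("total score has zero variance")
    p = x.mean(axis=0)
    return float(k / (k - 1) * (1.0 - np.sum(p * (1 - p)) / total_var))


def pearson_r(x, y) -> float:
    """Product-moment correlation; errors on constant input or n < 3."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with >= 3 persons")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant input has no defined correlation")
    return float(stats.pearsonr(x, y).statistic)


class TTestResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def two_sample_t(x_pos, x_neg, welch: bool = False) -> TTestResult:
    """Two-sample t test, pooled (Student) form by default, df = n1 + n2 - 2."""
    a = np.asarray(x_pos, dtype=float)
    b = np.asarray(x_neg, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 observations")
    res = stats.ttest_ind(a, b, equal_var=not welch)
    if not welch:
        pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
        if pooled == 0:
            raise ValueError("zero pooled variance")
        df = a.size + b.size - 2
    else:
        df = res.df
    return TTestResult(float(res.statistic), int(df), float(res.pvalue))


class MannWhitneyResult(NamedTuple):
    u_first: float     # pairs where the first group wins (+ half ties)
    u_second: float    # n_a * n_b - u_first
    pvalue: float


def mann_whitney_u(x_a, x_b) -> MannWhitneyResult:
    """Mann-Whitney U in both orientations (the reported convention varies)."""
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.size < 1 or b.size < 1:
        raise ValueError("each group needs >= 1 observation")
    res = stats.mannwhitneyu(a, b, alternative="two-sided")
    u_a = float(res.statistic)
    return MannWhitneyResult(u_a, a.size * b.size - u_a, float(res.pvalue))


class ChiSquareResult(NamedTuple):
    statistic: float
    df: int
    pvalue: float


def chi_square_independence(table) -> ChiSquareResult:
    """Pearson chi-square on an r x c count table, df = (r-1)(c-1).

    Rows/columns with a zero margin are dropped with a warning.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2:
        raise ValueError("need a 2-D count table")
    keep_r = t.sum(axis=1) > 0
    keep_c = t.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        logger.warning("dropping zero-margin rows/columns from the table")
        t = t[keep_r][:, keep_c]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table collapses below 2 x 2 after dropping zero margins")
    res = stats.chi2_contingency(t, correction=False)
    return ChiSquareResult(float(res.statistic), int(res.dof), float(res.pvalue))
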