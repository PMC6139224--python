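"""Shared statistical primitives.

Thin, validated wrappers around scipy/statsmodels routines that several
analysis layers use: Benjamini-Hochberg FDR adjustment, the Wilcoxon
rank-sum test (exact for small untied samples, normal approximation with
tie and continuity correction otherwise), and the Pearson product-moment
correlation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .exceptions import UndefinedCorrelationError, ValidationError

__all__ = [
    "benjamini_hochberg",
    "wilcoxon_rank_sum",
    "rank_sum_matrix",
    "pearson_correlation",
]

# exact enumeration is cheap and exact only makes sense without ties
_EXACT_MAX_N = 12


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Parameters
    ----------
    p_values : array-like of float in [0, 1]

    Returns
    -------
    ndarray of adjusted p-values, same order as the input.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when ``len(x) + len(y) <= 12`` and the
    data contain no ties; otherwise the normal approximation with tie and
    continuity correction.

    Returns
    -------
    (statistic, p_value)
        ``statistic`` is the rank sum of ``x`` (midranks under ties).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    nx, ny = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # every observation identical: no evidence either way
        return nx * (nx + 1) / 2 + nx * ny / 2, 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (nx + ny <= _EXACT_MAX_N and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    w = float(res.statistic) + nx * (nx + 1) / 2  # U -> rank sum of x
    return w, float(min(res.pvalue, 1.0))


def rank_sum_matrix(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rank-sum test for two groups of columns.

    Normal approximation with tie/continuity correction (the relevant
    regime for cohort-sized groups).  Rows that are entirely constant get
    p = 1.

    Parameters
    ----------
    x, y : 2-D arrays with one row per feature, columns = samples.

    Returns
    -------
    (w, p) per-row rank sums of ``x`` and two-sided p-values.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[1] == 0 or y.shape[1] == 0:
        raise ValidationError("both groups must be non-empty")
    nx = x.shape[1]
    pooled = np.concatenate([x, y], axis=1)
    constant = np.all(pooled == pooled[:, :1], axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=1,
        )
    w = np.asarray(res.statistic, dtype=float) + nx * (nx + 1) / 2
    p = np.asarray(res.pvalue, dtype=float)
    if constant.any():
        p[constant] = 1.0
        w[constant] = nx * (nx + 1) / 2 + nx * y.shape[1] / 2
    return w, np.minimum(p, 1.0)


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation coefficient.

    Raises
    ------
    UndefinedCorrelationError
        If either input has zero variance.
    ValidationError
        If lengths differ or fewer than 3 observations are given.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be 1-D and of equal length")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    return float(np.corrcoef(x, y)[0, 1])
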