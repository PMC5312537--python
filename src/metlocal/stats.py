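"""Shared statistical primitives used by every pipeline stage.

Correlation, two-group tests, multiple-testing control (Benjamini-Hochberg
and Storey q-values) and quantile normalization, with strict input
contracts: constant inputs raise instead of silently yielding NaN, and
p-values are validated to lie in [0, 1].
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ConstantInputError",
    "pearson_correlation",
    "spearman_correlation",
    "welch_t_test",
    "bh_adjust",
    "storey_qvalues",
    "quantile_normalize",
    "log2_fold_change",
]


class ConstantInputError(ValueError):
    """A statistic is undefined because an input vector has zero variance."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if np.isnan(arr).any():
        raise ValueError(f"{name} contains missing values")
    return arr


def pearson_correlation(x, y, feature: str | None = None) -> tuple[float, float]:
    """Pearson correlation with two-sided p-value.

    Requires at least 3 paired observations and non-constant inputs.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError(
            f"correlation undefined for constant input{f' ({feature})' if feature else ''}"
        )
    r = sps.pearsonr(x, y)
    return float(r.statistic), float(r.pvalue)


def spearman_correlation(x, y, feature: str | None = None) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p.

    The p-value uses the t-distribution approximation of the rank
    correlation, the convention appropriate for cohort-scale n.
    """
    x = _as_float_array(x, "x")
    y = _as_float_array(y, "y")
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError(
            f"correlation undefined for constant input{f' ({feature})' if feature else ''}"
        )
    r = sps.spearmanr(x, y)
    return float(r.statistic), float(r.pvalue)


def welch_t_test(a, b) -> tuple[float, float]:
    """Unpaired heteroscedastic (Welch) t-test, two-sided.

    Degrees of freedom follow Welch-Satterthwaite. Both groups having zero
    variance makes the statistic undefined (0/0 for equal means, infinite
    for unequal means); both cases raise.
    """
    a = _as_float_array(a, "a")
    b = _as_float_array(b, "b")
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        raise ConstantInputError("t statistic undefined: both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def _validate_pvalues(p) -> np.ndarray:
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        raise ValueError("empty p-value vector")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1] with no missing entries")
    return arr


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    arr = _validate_pvalues(p)
    return multipletests(arr, method="fdr_bh")[1]


def storey_qvalues(p, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with fixed-lambda pi0 estimate.

    pi0 = min(1, #{p > lambda} / ((1 - lambda) * n)); q-values are the
    BH-style cumulative-minimum transform scaled by pi0. Monotone in p.
    """
    arr = _validate_pvalues(p)
    if not 0 < lam < 1:
        raise ValueError("lambda must be in (0, 1)")
    n = arr.size
    pi0 = min(1.0, np.count_nonzero(arr > lam) / ((1.0 - lam) * n))
    order = np.argsort(arr, kind="mergesort")
    ranks = np.arange(1, n + 1)
    q_sorted = pi0 * arr[order] * n / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.clip(q_sorted, 0.0, 1.0)
    return q


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize a features x samples matrix.

    Every column is mapped onto the common reference distribution given by
    the row means of the column-sorted matrix. Ties within a column receive
    the mean of the reference values at their tied ranks, so tied inputs
    stay tied.
    """
    if matrix.isna().any().any():
        raise ValueError("matrix contains missing values; imputation is out of scope")
    values = matrix.to_numpy(dtype=float)
    n_rows, n_cols = values.shape
    if n_cols < 1:
        raise ValueError("need at least one sample column")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(n_cols):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_col = col[order]
        # run starts of tied values in sorted order
        starts = np.flatnonzero(np.r_[True, sorted_col[1:] != sorted_col[:-1]])
        sums = np.add.reduceat(reference, starts)
        lengths = np.diff(np.r_[starts, n_rows])
        tie_means = sums / lengths
        assigned = np.repeat(tie_means, lengths)
        out[order, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def log2_fold_change(old, young) -> float:
    """Mean difference old - young; inputs are assumed already on log2 scale."""
    old = _as_float_array(old, "old")
    young = _as_float_array(young, "young")
    if len(old) == 0 or len(young) == 0:
        raise ValueError("empty group")
    return float(old.mean() - young.mean())
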