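"""Statistical primitives: frozen worked examples plus distributional and
order-preservation properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from metlocal.stats import (
    ConstantInputError,
    bh_adjust,
    log2_fold_change,
    pearson_correlation,
    quantile_normalize,
    spearman_correlation,
    storey_qvalues,
    welch_t_test,
)

finite_floats = st.floats(
    min_value=-1e6, max_value=1e6, allow_nan=False, allow_infinity=False
)


@pytest.mark.parametrize(
    "func, x, y, expected_rho",
    [
        (pearson_correlation, [1, 2, 3], [2, 4, 6], 1.0),
        (pearson_correlation, [1, 2, 3], [6, 4, 2], -1.0),
        (pearson_correlation, [1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        (spearman_correlation, [1, 2, 5], [10, 20, 21], 1.0),
        (spearman_correlation, [1, 2, 3, 4], [4, 3, 2, 1], -1.0),
        (spearman_correlation, [1, 2, 3, 4], [1, 3, 2, 4], 0.8),
    ],
)
def test_correlation_worked_examples(func, x, y, expected_rho):
    rho, p = func(x, y)
    assert rho == pytest.approx(expected_rho, abs=1e-12)
    assert 0.0 <= p <= 1.0


def test_spearman_is_pearson_on_ranks():
    rng = np.random.default_rng(3)
    x = rng.permutation(20).astype(float)  # rank-valued, no ties
    y = rng.permutation(20).astype(float)
    rho_s, _ = spearman_correlation(x, y)
    rho_p, _ = pearson_correlation(x, y)
    assert rho_s == pytest.approx(rho_p, abs=1e-12)


@pytest.mark.parametrize("func", [pearson_correlation, spearman_correlation])
def test_correlation_constant_input_raises_naming_feature(func):
    with pytest.raises(ConstantInputError, match="ion42"):
        func([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], feature="ion42")


def test_welch_identical_groups():
    t, p = welch_t_test([1, 2, 3], [1, 2, 3])
    assert t == pytest.approx(0.0, abs=1e-12)
    assert p == pytest.approx(1.0, abs=1e-12)


def test_welch_worked_example():
    # equal variances 5/3, mean difference -2: t = -2 / sqrt(5/6)
    t, p = welch_t_test([1, 2, 3, 4], [3, 4, 5, 6])
    assert t == pytest.approx(-2.190890, abs=1e-5)
    assert 0 < p < 0.1


@pytest.mark.parametrize("a, b", [([5, 5], [5, 5]), ([5, 5], [7, 7])])
def test_welch_degenerate_variance_raises(a, b):
    with pytest.raises(ConstantInputError):
        welch_t_test(a, b)


def test_welch_null_pvalues_uniform():
    """Under equal-mean Gaussian groups the Welch p-value is uniform."""
    rng = np.random.default_rng(2024)
    a = rng.normal(size=(5000, 10))
    b = rng.normal(size=(5000, 10))
    p = sps.ttest_ind(a, b, axis=1, equal_var=False).pvalue
    assert sps.kstest(p, "uniform").pvalue > 0.01


@pytest.mark.parametrize(
    "p, expected",
    [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_worked_examples(p, expected):
    np.testing.assert_allclose(bh_adjust(p), expected, atol=1e-12)


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.5])


def test_storey_all_ones():
    np.testing.assert_allclose(storey_qvalues([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])


def test_storey_worked_example():
    q = storey_qvalues([0.01, 0.2, 0.6, 0.8], lam=0.5)
    np.testing.assert_allclose(q, [0.04, 0.4, 0.8, 0.8], atol=1e-12)


def test_storey_empty_raises():
    with pytest.raises(ValueError):
        storey_qvalues([])


@settings(max_examples=60, derandomize=True, deadline=None)
@given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
def test_fdr_adjustments_preserve_order_and_bounds(p):
    p = np.asarray(p)
    bh = bh_adjust(p)
    q = storey_qvalues(p)
    pi0 = min(1.0, np.mean(p > 0.5) / 0.5) if len(p) else 1.0
    order = np.argsort(p, kind="mergesort")
    assert np.all(np.diff(bh[order]) >= -1e-12)
    assert np.all(np.diff(q[order]) >= -1e-12)
    assert np.all(bh >= p - 1e-12)  # BH never drops below the raw p
    assert np.all(q >= pi0 * p - 1e-12)
    assert np.all((q >= 0) & (q <= 1)) and np.all(bh <= 1)


def test_storey_dominates_scaled_bh():
    rng = np.random.default_rng(5)
    p = rng.uniform(size=200)
    pi0 = min(1.0, np.mean(p > 0.5) / 0.5)
    np.testing.assert_allclose(storey_qvalues(p), pi0 * bh_adjust(p), atol=1e-12)


def test_quantile_normalize_worked_example():
    mat = pd.DataFrame({"s1": [5.0, 2.0, 3.0], "s2": [4.0, 1.0, 2.0]})
    out = quantile_normalize(mat)
    np.testing.assert_allclose(out["s1"], [4.5, 1.5, 2.5])
    np.testing.assert_allclose(out["s2"], [4.5, 1.5, 2.5])


def test_quantile_normalize_identity_cases():
    single = pd.DataFrame({"s1": [3.0, 1.0, 7.0]})
    pd.testing.assert_frame_equal(quantile_normalize(single), single)
    same = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
    pd.testing.assert_frame_equal(quantile_normalize(same), same)


def test_quantile_normalize_ties_get_mean_reference():
    # reference is [1.5, 2.5, 4.5]; the tied pair in s1 spans ranks 1-2
    mat = pd.DataFrame({"s1": [1.0, 1.0, 9.0], "s2": [1.0, 2.0, 4.0], "s3": [2.0, 3.0, 5.0]})
    out = quantile_normalize(mat)
    ref = np.sort(mat.to_numpy(), axis=0).mean(axis=1)
    assert out["s1"].iloc[0] == out["s1"].iloc[1] == pytest.approx(ref[:2].mean())
    assert out["s1"].iloc[2] == pytest.approx(ref[2])


def test_quantile_normalize_rejects_missing():
    with pytest.raises(ValueError):
        quantile_normalize(pd.DataFrame({"a": [1.0, np.nan]}))


@settings(max_examples=40, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_quantile_normalize_idempotent_with_common_columns(seed):
    rng = np.random.default_rng(seed)
    mat = pd.DataFrame(rng.normal(size=(15, 4)), columns=list("abcd"))
    once = quantile_normalize(mat)
    twice = quantile_normalize(once)
    np.testing.assert_allclose(once.to_numpy(), twice.to_numpy(), atol=1e-12)
    cols = np.sort(once.to_numpy(), axis=0)
    np.testing.assert_allclose(cols, cols[:, [0]] * np.ones(4), atol=1e-12)


@pytest.mark.parametrize(
    "old, young, expected",
    [([2, 4], [2, 4], 0.0), ([3, 3], [2, 2], 1.0), ([2, 4], [1, 3], 1.0)],
)
def test_log2_fold_change(old, young, expected):
    assert log2_fold_change(old, young) == pytest.approx(expected)


def test_log2_fold_change_empty_group_raises():
    with pytest.raises(ValueError):
        log2_fold_change([], [1.0])
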