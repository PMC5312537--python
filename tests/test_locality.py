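"""Locality score: formula identities, invariances, exhaustive-permutation
oracle and the published hit-filter rules."""

from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from metlocal.locality import (
    filter_locality_hits,
    locality_analysis,
    locality_score,
    locality_scores,
    permutation_null,
    spearman_matrix,
)


def test_single_neighbor_score_is_abs_correlation():
    for d in (1.0, 2.0, 7.0):
        assert locality_score([0.5], [0.2], [d]) == pytest.approx(0.5, abs=1e-12)
        assert locality_score([-0.5], [0.2], [d]) == pytest.approx(0.5, abs=1e-12)


def test_zero_correlations_give_zero_score():
    assert locality_score([0.0, 0.0, 0.0], [0.5, 0.2, 0.9], [1, 2, 3]) == 0.0


def test_two_neighbor_worked_example():
    # (1*0.99*0.8 + 0.25*0.5*0.2) / (0.99 + 0.125) = 0.817/1.115
    s = locality_score([0.8, 0.2], [0.01, 0.5], [1.0, 2.0])
    assert s == pytest.approx(0.817 / 1.115, abs=1e-12)
    assert s == pytest.approx(0.7327, abs=1e-4)


def test_score_bounded_and_metabolite_relabeling_invariant(rng):
    C = rng.uniform(-1, 1, size=12)
    P = rng.uniform(0, 1, size=12)
    D = rng.integers(1, 6, size=12).astype(float)
    s = locality_score(C, P, D)
    assert 0.0 <= s <= 1.0
    perm = rng.permutation(12)
    assert locality_score(C[perm], P[perm], D[perm]) == pytest.approx(s, abs=1e-12)


def test_unreachable_metabolites_carry_zero_weight():
    s = locality_score([0.9, 0.1], [0.01, 0.01], [1.0, np.inf])
    assert s == pytest.approx(0.9, abs=1e-12)


def test_d_max_truncates_neighborhood():
    s = locality_score([0.9, 0.1], [0.01, 0.01], [1.0, 5.0], d_max=2)
    assert s == pytest.approx(0.9, abs=1e-12)


def test_empty_neighborhood_raises():
    with pytest.raises(ValueError):
        locality_score([0.5], [0.2], [np.inf])


def test_spearman_matrix_agrees_with_scipy(rng):
    X = rng.normal(size=(4, 15))
    Y = rng.normal(size=(6, 15))
    C, P = spearman_matrix(X, Y)
    for i in range(4):
        for j in range(6):
            ref = sps.spearmanr(X[i], Y[j])
            assert C[i, j] == pytest.approx(ref.statistic, abs=1e-12)
            assert P[i, j] == pytest.approx(ref.pvalue, abs=1e-10)


def test_equal_distances_make_every_permutation_tie():
    C = np.array([[0.8, 0.1, 0.4]])
    P = np.array([[0.1, 0.5, 0.3]])
    D = np.full((1, 3), 2.0)
    _, p, _ = permutation_null(C, P, D, K=50, seed=0)
    assert p[0] == pytest.approx(1.0)


def test_score_below_every_permutation_gives_p_one():
    # strongest correlation farthest away: the identity is the worst pairing
    C = np.array([[0.05, 0.95]])
    P = np.array([[0.5, 0.01]])
    D = np.array([[1.0, 4.0]])
    _, p, _ = permutation_null(C, P, D, K=100, seed=0)
    assert p[0] == pytest.approx(1.0)


def exhaustive_p(C, P, D):
    """Enumerate all column permutations of D for a single transcript."""
    s = locality_score(C, P, D)
    hits, total = 0, 0
    for perm in permutations(range(len(D))):
        total += 1
        if locality_score(C, P, D[list(perm)]) >= s - 1e-12:
            hits += 1
    return hits / total


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_monte_carlo_matches_exhaustive_permutations(seed):
    rng = np.random.default_rng(seed)
    m = 4
    C = rng.uniform(-1, 1, size=(1, m))
    P = rng.uniform(0, 1, size=(1, m))
    D = rng.integers(1, 5, size=(1, m)).astype(float)
    exact = exhaustive_p(C[0], P[0], D[0])
    K = 4000
    _, p_mc, _ = permutation_null(C, P, D, K=K, seed=seed)
    se = np.sqrt(exact * (1 - exact) / K)
    assert abs(p_mc[0] - exact) <= max(3 * se, 1e-9)


def test_per_row_scheme_matches_shared_for_single_transcript():
    rng = np.random.default_rng(8)
    C = rng.uniform(-1, 1, size=(1, 5))
    P = rng.uniform(0, 1, size=(1, 5))
    D = rng.integers(1, 4, size=(1, 5)).astype(float)
    _, p_shared, _ = permutation_null(C, P, D, K=3000, seed=0, scheme="shared")
    _, p_row, _ = permutation_null(C, P, D, K=3000, seed=0, scheme="per_row")
    exact = exhaustive_p(C[0], P[0], D[0])
    assert abs(p_shared[0] - exact) <= 0.05 and abs(p_row[0] - exact) <= 0.05


def test_locality_analysis_smoke(small_study):
    from metlocal.network import enzyme_metabolite_distances

    expr = small_study["expression"]
    intens = small_study["intensities"]
    db = small_study["db"]
    network = small_study["network"]
    met_levels = np.log2(intens.iloc[: len(db)].copy())
    met_levels.index = db["compound_id"]
    distances = enzyme_metabolite_distances(network, met_levels.index)
    res = locality_analysis(expr, met_levels, distances, K=200, seed=0)
    assert res["S"].between(0, 1).all()
    assert res["p_locality"].between(0, 1).all()
    assert (res["K"] == 200).all()


REFERENCE_COLUMNS = ["p_locality", "p_age", "adj_p"]


@pytest.mark.parametrize(
    "row, retained",
    [
        # top reference hit: passes both age branches
        ({"p_locality": 1e-4, "p_age": 0.026, "adj_p": 0.006}, True),
        # passes only via the differential branch (gene-age p just over 0.1)
        ({"p_locality": 0.032, "p_age": 0.101, "adj_p": 0.077}, True),
        # locality gate fails although both age tests pass
        ({"p_locality": 0.06, "p_age": 0.01, "adj_p": 0.01}, False),
        # locality passes but no age-dependence evidence
        ({"p_locality": 0.01, "p_age": 0.5, "adj_p": 0.5}, False),
        # boundary: thresholds are strict
        ({"p_locality": 0.05, "p_age": 0.01, "adj_p": 0.01}, False),
    ],
)
def test_hit_filter_rules(row, retained):
    df = pd.DataFrame([row], index=["g"])
    out = filter_locality_hits(df)
    assert ("g" in out.index) is retained


def test_hit_filter_sorts_by_locality_p():
    df = pd.DataFrame(
        {"p_locality": [0.03, 0.001], "p_age": [0.05, 0.05], "adj_p": [0.5, 0.5]},
        index=["slow", "fast"],
    )
    assert list(filter_locality_hits(df).index) == ["fast", "slow"]


def test_hit_filter_requires_columns():
    with pytest.raises(ValueError):
        filter_locality_hits(pd.DataFrame({"p_locality": [0.01]}))
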