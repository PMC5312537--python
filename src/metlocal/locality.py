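"""Network locality score for metabolic enzymes.

An enzyme whose age-dependent expression change is functional should leave a
footprint on the metabolites around it in the metabolic network. The
locality score of transcript t_i is the weighted mean of the absolute
Spearman correlation |C_{i,m}| between its expression and each metabolite's
level,

    S(t_i) = sum_m D_{i,m}^-2 (1 - p_{C_{i,m}}) |C_{i,m}|
             -----------------------------------------------
             sum_m D_{i,m}^-2 (1 - p_{C_{i,m}})

with D the enzyme-metabolite network distance, so proximal and confidently
estimated correlations dominate. Significance comes from K random
permutations of the distance matrix columns: correlations stay fixed, only
the distance-to-metabolite pairing is broken, and

    p(S(t_i)) = #{ S_rand^k(t_i) >= S(t_i) } / K.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "spearman_matrix",
    "locality_score",
    "locality_scores",
    "permutation_null",
    "locality_analysis",
    "filter_locality_hits",
]

_EQ_TOL = 1e-12  # "greater or equal" comparisons between permuted and real scores


def spearman_matrix(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Spearman correlations between rows of X and rows of Y.

    Returns (C, P) with the t-approximation two-sided p-values. Rows with
    zero variance produce NaN columns/rows (handled as zero weight by the
    scoring functions).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n = X.shape[1]
    if Y.shape[1] != n:
        raise ValueError("sample dimensions differ")
    if n < 3:
        raise ValueError("need at least 3 matched samples")
    rx = sps.rankdata(X, axis=1)
    ry = sps.rankdata(Y, axis=1)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean(axis=1, keepdims=True)
    sx = np.sqrt((rx**2).sum(axis=1))
    sy = np.sqrt((ry**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        C = (rx @ ry.T) / np.outer(sx, sy)
    C = np.clip(C, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = C * np.sqrt((n - 2) / (1.0 - C**2))
    P = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    P = np.where(np.abs(C) >= 1.0, 0.0, P)
    return C, P


def _weight_parts(C: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Distance-free weight factors: A = (1-p)|C|, B = (1-p); NaN -> 0."""
    A = (1.0 - P) * np.abs(C)
    B = 1.0 - P
    bad = ~np.isfinite(C)
    A[bad] = 0.0
    B[bad] = 0.0
    return A, B


def _inv_sq(D: np.ndarray, d_max: float | None) -> np.ndarray:
    """D^-2 with unreachable (inf) and beyond-d_max entries zeroed."""
    D = np.asarray(D, dtype=float)
    valid = np.isfinite(D) & (D > 0)
    if d_max is not None and d_max > 0:
        valid &= D <= d_max
    out = np.zeros_like(D)
    out[valid] = D[valid] ** -2
    return out


def locality_score(C, p_C, D, d_max: float | None = None) -> float:
    """Score one transcript from its per-metabolite correlations and distances."""
    C = np.asarray(C, dtype=float)
    P = np.asarray(p_C, dtype=float)
    w = _inv_sq(D, d_max)
    A, B = _weight_parts(C[None, :], P[None, :])
    denom = float((w * B[0]).sum())
    if denom <= 0:
        raise ValueError("empty neighborhood: no reachable metabolite with defined correlation")
    return float((w * A[0]).sum() / denom)


def locality_scores(C: np.ndarray, P: np.ndarray, D: np.ndarray,
                    d_max: float | None = None) -> np.ndarray:
    """Vectorized scores for all transcripts; NaN where the neighborhood is empty."""
    w = _inv_sq(D, d_max)
    A, B = _weight_parts(C, P)
    num = (w * A).sum(axis=1)
    den = (w * B).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(den > 0, num / den, np.nan)


def permutation_null(
    C: np.ndarray,
    P: np.ndarray,
    D: np.ndarray,
    K: int = 10000,
    seed: int | np.random.Generator = 0,
    d_max: float | None = None,
    scheme: str = "shared",
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Permutation p-values for the locality scores.

    Each iteration applies one random permutation of the metabolite indices
    to the columns of D (shared across transcripts; `scheme="per_row"`
    shuffles each row independently). Correlations are never recomputed —
    only the distance weights are reassigned. Returns (S, p, K_effective).
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    w = _inv_sq(D, d_max)
    A, B = _weight_parts(C, P)
    num = (w * A).sum(axis=1)
    den = (w * B).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(den > 0, num / den, np.nan)
    n_t, n_m = w.shape
    count = np.zeros(n_t)
    k_eff = np.zeros(n_t)
    for _ in range(K):
        if scheme == "shared":
            wp = w[:, rng.permutation(n_m)]
        elif scheme == "per_row":
            wp = np.take_along_axis(
                w, np.argsort(rng.random((n_t, n_m)), axis=1), axis=1
            )
        else:
            raise ValueError(f"unknown permutation scheme {scheme!r}")
        num_k = (wp * A).sum(axis=1)
        den_k = (wp * B).sum(axis=1)
        ok = den_k > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            S_k = num_k / den_k
        hit = ok & (S_k >= S - _EQ_TOL)
        count += hit
        k_eff += ok
    dropped = int((k_eff < K).sum())
    if dropped:
        logger.warning("%d transcripts had permutations skipped (empty neighborhood)", dropped)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(k_eff > 0, count / k_eff, np.nan)
    return S, p, k_eff


def locality_analysis(
    expression: pd.DataFrame,
    metabolite_levels: pd.DataFrame,
    distances: pd.DataFrame,
    K: int = 10000,
    seed: int | np.random.Generator = 0,
    d_max: float | None = None,
    scheme: str = "shared",
) -> pd.DataFrame:
    """Score every enzyme transcript against the measured metabolome.

    `expression`: gene-collapsed transcript profiles (genes x samples);
    `metabolite_levels`: metabolite x samples (same sample order);
    `distances`: enzymes x metabolites from enzyme_metabolite_distances.
    Returns a table indexed by transcript with S, p_locality and K.
    """
    enzymes = [e for e in distances.index if e in expression.index]
    skipped = [e for e in distances.index if e not in expression.index]
    if skipped:
        logger.warning("%d enzymes lack expression profiles; skipped", len(skipped))
    mets = [m for m in distances.columns if m in metabolite_levels.index]
    if not mets or not enzymes:
        raise ValueError("no overlap between distance matrix and measured profiles")
    samples = list(expression.columns)
    if list(metabolite_levels.columns) != samples:
        metabolite_levels = metabolite_levels[samples]
    X = expression.loc[enzymes].to_numpy()
    Y = metabolite_levels.loc[mets].to_numpy()
    D = distances.loc[enzymes, mets].to_numpy()
    C, P = spearman_matrix(X, Y)
    S, p, k_eff = permutation_null(C, P, D, K=K, seed=seed, d_max=d_max, scheme=scheme)
    out = pd.DataFrame(
        {"S": S, "p_locality": p, "K": k_eff.astype(int)},
        index=pd.Index(enzymes, name="transcript"),
    )
    empty = out["S"].isna()
    if empty.any():
        logger.warning("%d transcripts had empty neighborhoods; dropped", int(empty.sum()))
        out = out[~empty]
    return out


def filter_locality_hits(
    results: pd.DataFrame,
    p_locality_max: float = 0.05,
    p_age_max: float = 0.1,
    adj_p_max: float = 0.1,
) -> pd.DataFrame:
    """Functional hits with age-dependent expression.

    Retains transcripts with locality p < 0.05 AND age-dependent expression
    (Spearman gene-age p < 0.1, or BH-adjusted differential p < 0.1).
    Expects columns p_locality, p_age and adj_p; returns rows sorted by
    ascending p_locality.
    """
    required = {"p_locality", "p_age", "adj_p"}
    missing = required - set(results.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    keep = (results["p_locality"] < p_locality_max) & (
        (results["p_age"] < p_age_max) | (results["adj_p"] < adj_p_max)
    )
    return results[keep].sort_values("p_locality", kind="mergesort")
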