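"""Recursive nested-subset hypergeometric pathway enrichment.

Significant features are ranked best-first; for each pathway the
hypergeometric upper tail is evaluated on every prefix of that ranking (the
most significant feature alone, the best two, ... up to the full significant
set) and the minimum over prefixes is the pathway's enrichment p-value.
Pathway p-values are then FDR-corrected with Storey q-values.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .stats import storey_qvalues

logger = logging.getLogger(__name__)

__all__ = ["hypergeometric_tail", "recursive_enrichment", "enrichment_fdr"]


def hypergeometric_tail(
    ptw_hits: int,
    total_all_detected: int,
    ptw_all_detected: int,
    total_hits: int,
    pmf_only: bool = False,
) -> float:
    """P(X >= ptw_hits) drawing total_hits from a background of
    total_all_detected containing ptw_all_detected pathway members.

    `pmf_only` returns the single point mass P(X = ptw_hits) instead of the
    upper tail (the literal overlap term rather than a p-value).
    """
    if not (
        0 <= ptw_hits <= min(ptw_all_detected, total_hits)
        and ptw_all_detected <= total_all_detected
        and total_hits <= total_all_detected
    ):
        raise ValueError(
            f"inconsistent counts: hits={ptw_hits}, background={total_all_detected}, "
            f"pathway={ptw_all_detected}, total_hits={total_hits}"
        )
    dist = hypergeom(total_all_detected, ptw_all_detected, total_hits)
    if pmf_only:
        return float(dist.pmf(ptw_hits))
    return float(dist.sf(ptw_hits - 1))


def recursive_enrichment(
    ranked_hits,
    pathways: dict[str, set] | pd.DataFrame,
    background,
    pmf_only: bool = False,
) -> pd.DataFrame:
    """Best prefix p-value per pathway.

    `ranked_hits` must be sorted most-significant first and be a subset of
    `background`. Pathway memberships are intersected with the background
    before counting. Returns a table (pathway_id index) with best_p,
    best_subset_size and the count columns at the best prefix.
    """
    if isinstance(pathways, pd.DataFrame):
        pathways = {
            pw: set(grp["member_id"]) for pw, grp in pathways.groupby("pathway_id")
        }
    background = set(background)
    ranked_hits = list(ranked_hits)
    stray = [h for h in ranked_hits if h not in background]
    if stray:
        raise ValueError(f"hits outside the background: {stray[:5]}")
    if not ranked_hits:
        logger.warning("empty hit list; no enrichment computed")
        return pd.DataFrame(
            columns=["best_p", "best_subset_size", "ptw_hits", "ptw_all_detected"]
        ).rename_axis("pathway_id")
    n_bg = len(background)
    rows = {}
    for pw, members in sorted(pathways.items()):
        members_bg = members & background
        m = len(members_bg)
        best_p, best_k, best_hits = 1.0, len(ranked_hits), 0
        in_pathway = 0
        for k, hit in enumerate(ranked_hits, start=1):
            if hit in members_bg:
                in_pathway += 1
            p = hypergeometric_tail(in_pathway, n_bg, m, k, pmf_only=pmf_only)
            if p < best_p - 1e-15:
                best_p, best_k, best_hits = p, k, in_pathway
        rows[pw] = {
            "best_p": best_p,
            "best_subset_size": best_k,
            "ptw_hits": best_hits,
            "ptw_all_detected": m,
        }
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("pathway_id")


def enrichment_fdr(results: pd.DataFrame, q_max: float = 0.01) -> pd.DataFrame:
    """Storey q-values over all tested pathways plus a significance flag."""
    out = results.copy()
    if len(out) == 0:
        out["q"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out
    out["q"] = storey_qvalues(out["best_p"].to_numpy())
    out["significant"] = out["q"] < q_max
    return out
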