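"""Transcriptome stage: QC filtering, normalization, differential expression.

Microarray features carrying a saturated or background-level signal in at
least half the samples are removed, the remaining features are
quantile-normalized, and old-vs-young differences are assessed per feature
with an ordinary two-group linear model (a pooled-variance t-test on the
group indicator) under Benjamini-Hochberg FDR control. Spearman correlation
of each feature with donor age is computed alongside, since the downstream
locality hit filter uses it.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats

logger = logging.getLogger(__name__)

__all__ = [
    "qc_filter_features",
    "differential_expression",
    "significant_transcripts",
    "map_to_metabolic_genes",
    "collapse_to_genes",
]


def qc_filter_features(
    matrix: pd.DataFrame,
    flags: pd.DataFrame | None,
    max_bad_fraction: float = 0.5,
) -> pd.DataFrame:
    """Drop features flagged saturated/background in >= max_bad_fraction of samples.

    The boundary is inclusive: a feature bad in exactly half the samples is
    removed.
    """
    if flags is None:
        return matrix
    flags = flags.loc[matrix.index, matrix.columns]
    bad = flags.isin(["saturated", "background"]).sum(axis=1) / matrix.shape[1]
    keep = bad < max_bad_fraction
    logger.info("QC filter: %d of %d features kept", int(keep.sum()), len(matrix))
    return matrix[keep]


def differential_expression(matrix: pd.DataFrame, donors: pd.DataFrame) -> pd.DataFrame:
    """Per-feature two-group linear model plus gene-age Spearman correlation.

    The group-indicator OLS coefficient test is algebraically the
    pooled-variance t-test, computed here in that form. log2fc is the group
    coefficient (old minus young); BH adjustment runs over all retained
    features.
    """
    donors = donors.set_index("donor_id") if "donor_id" in donors.columns else donors
    missing = set(matrix.columns) - set(donors.index)
    if missing:
        raise ValueError(f"samples without donor entry: {sorted(missing)}")
    info = donors.loc[list(matrix.columns)]
    groups = info["group"].to_numpy()
    age = info["age"].to_numpy(dtype=float)
    values = matrix.to_numpy(dtype=float)
    old = values[:, groups == "old"]
    young = values[:, groups == "young"]
    if old.shape[1] < 2 or young.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    res = sps.ttest_ind(old, young, axis=1, equal_var=True)
    p = np.asarray(res.pvalue, dtype=float)
    defined = np.isfinite(p)
    adj = np.full(len(matrix), np.nan)
    if defined.any():
        adj[defined] = stats.bh_adjust(p[defined])
    if not defined.all():
        logger.warning("%d zero-variance features excluded from BH family",
                       int((~defined).sum()))

    # Spearman of each feature with age, t-approximation p-values
    n = values.shape[1]
    r_feat = sps.rankdata(values, axis=1)
    r_age = sps.rankdata(age)
    r_feat = r_feat - r_feat.mean(axis=1, keepdims=True)
    r_age = r_age - r_age.mean()
    denom = np.sqrt((r_feat**2).sum(axis=1)) * np.sqrt((r_age**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.clip(r_feat @ r_age / denom, -1.0, 1.0)
        t_age = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p_age = np.where(np.abs(rho) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t_age), df=n - 2))
    p_age = np.where(np.isfinite(rho), p_age, np.nan)

    return pd.DataFrame(
        {
            "log2fc": old.mean(axis=1) - young.mean(axis=1),
            "t": np.asarray(res.statistic, dtype=float),
            "p": p,
            "adj_p": adj,
            "rho_age": rho,
            "p_age": p_age,
        },
        index=matrix.index,
    )


def significant_transcripts(
    results: pd.DataFrame, fc_min: float = 0.25, p_max: float = 0.01
) -> pd.DataFrame:
    """Features with |log2FC| strictly above fc_min and BH-adjusted p below p_max."""
    keep = (results["log2fc"].abs() > fc_min) & (results["adj_p"] < p_max)
    out = results[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def map_to_metabolic_genes(
    features, gene_pathway_map: pd.DataFrame | dict
) -> list:
    """Restrict features to those whose gene occurs in a metabolic pathway.

    `gene_pathway_map` is either a pathway_id/member_id table or a mapping
    gene -> pathways. Unknown symbols pass through as unmapped (a count is
    logged); the returned subset preserves input order.
    """
    if isinstance(gene_pathway_map, pd.DataFrame):
        metabolic = set(gene_pathway_map["member_id"])
    else:
        metabolic = {g for g, pws in gene_pathway_map.items() if pws}
    features = list(features)
    subset = [f for f in features if f in metabolic]
    logger.info("%d of %d features map to metabolic pathways", len(subset), len(features))
    return subset


def collapse_to_genes(matrix: pd.DataFrame, gene_symbols: pd.Series | None = None) -> pd.DataFrame:
    """One profile per gene symbol: the feature with the largest mean expression.

    With no symbol map, feature ids are taken as gene symbols already.
    """
    if gene_symbols is None:
        return matrix
    symbols = gene_symbols.loc[matrix.index]
    means = matrix.mean(axis=1)
    chooser = pd.DataFrame({"symbol": symbols, "mean": means})
    best = chooser.sort_values("mean", ascending=False).groupby("symbol", sort=False).head(1)
    collapsed = matrix.loc[best.index]
    collapsed.index = pd.Index(best["symbol"], name="gene")
    return collapsed.sort_index()
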