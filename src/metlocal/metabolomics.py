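"""Metabolome stage: ion annotation, normalization, age statistics.

Untargeted flow-injection data arrive as an ions x samples intensity matrix
with one m/z per ion. Ions are putatively annotated by exact mass against a
compound database, considering the deprotonated [M-H]- and fluoride-adducted
[M+F]- forms at 0.001 Da accuracy. Intensities are quantile-normalized and
log2-transformed before Pearson correlation with donor age and Welch
old-vs-young tests, with Storey q-value FDR control over the full ion family.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import stats

logger = logging.getLogger(__name__)

PROTON_MASS = 1.007276
FLUORIDE_MASS = 18.998403
ADDUCT_SHIFTS = {"[M-H]-": -PROTON_MASS, "[M+F]-": +FLUORIDE_MASS}

__all__ = [
    "annotate_ions",
    "normalize_intensities",
    "correlate_with_age",
    "significant_ions_correlation",
    "differential_metabolites",
    "significant_ions_differential",
]


def annotate_ions(
    ion_mz: pd.Series,
    db: pd.DataFrame,
    tolerance: float = 0.001,
    adducts=("[M-H]-", "[M+F]-"),
) -> pd.DataFrame:
    """Exact-mass annotation of ions against a compound database.

    For each ion, candidates are every compound whose adduct m/z (neutral
    mass shifted by the adduct) lies within `tolerance` Da of the observed
    m/z. Ions with no candidate stay unannotated but remain in all
    downstream statistics as detected ions. Returns long-format rows
    (ion_id, compound_id, adduct, mass_error) with mass_error = observed -
    theoretical.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    unknown = set(adducts) - set(ADDUCT_SHIFTS)
    if unknown:
        raise ValueError(f"unknown adducts: {sorted(unknown)}")
    rows = []
    masses = db["mass"].to_numpy(dtype=float)
    compounds = db["compound_id"].to_numpy()
    for ion_id, mz in ion_mz.items():
        for adduct in adducts:
            theo = masses + ADDUCT_SHIFTS[adduct]
            err = mz - theo
            hits = np.flatnonzero(np.abs(err) <= tolerance)
            for h in hits:
                rows.append(
                    {
                        "ion_id": ion_id,
                        "compound_id": compounds[h],
                        "adduct": adduct,
                        "mass_error": float(err[h]),
                    }
                )
    return pd.DataFrame(rows, columns=["ion_id", "compound_id", "adduct", "mass_error"])


def normalize_intensities(intensities: pd.DataFrame, log_transform: bool = True) -> pd.DataFrame:
    """Quantile normalization on the raw scale, then log2(x+1) for statistics."""
    norm = stats.quantile_normalize(intensities)
    if log_transform:
        norm = np.log2(norm + 1.0)
    return norm


def _match_donors(matrix: pd.DataFrame, donors: pd.DataFrame) -> pd.DataFrame:
    donors = donors.set_index("donor_id") if "donor_id" in donors.columns else donors
    missing = set(matrix.columns) - set(donors.index)
    if missing:
        raise ValueError(f"samples without donor entry: {sorted(missing)}")
    return donors.loc[list(matrix.columns)]


def correlate_with_age(matrix: pd.DataFrame, donors: pd.DataFrame) -> pd.DataFrame:
    """Per-ion Pearson correlation with donor age; Storey q over all ions.

    Constant ions have no defined correlation; they are excluded from the
    multiple-testing family and reported with NaN, with a logged warning.
    """
    donor_info = _match_donors(matrix, donors)
    age = donor_info["age"].to_numpy(dtype=float)
    values = matrix.to_numpy(dtype=float)
    constant = np.ptp(values, axis=1) == 0
    if constant.any():
        logger.warning("%d constant ions excluded from the correlation family",
                       int(constant.sum()))
    rho = np.full(len(matrix), np.nan)
    p = np.full(len(matrix), np.nan)
    n = values.shape[1]
    ok = ~constant
    centered = values[ok] - values[ok].mean(axis=1, keepdims=True)
    age_c = age - age.mean()
    denom = np.sqrt((centered**2).sum(axis=1)) * np.sqrt((age_c**2).sum())
    r = np.clip(centered @ age_c / denom, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    pv = np.where(np.abs(r) >= 1.0, 0.0, 2.0 * sps.t.sf(np.abs(t), df=n - 2))
    rho[ok], p[ok] = r, pv
    q = np.full(len(matrix), np.nan)
    if ok.any():
        q[ok] = stats.storey_qvalues(p[ok])
    return pd.DataFrame(
        {"rho_age": rho, "p_age": p, "q_age": q}, index=matrix.index
    )


def significant_ions_correlation(
    results: pd.DataFrame, rho_min: float = 0.25, q_max: float = 0.01
) -> pd.DataFrame:
    """Ions with |rho| strictly above rho_min and q below q_max, signed."""
    keep = (results["rho_age"].abs() > rho_min) & (results["q_age"] < q_max)
    out = results[keep].copy()
    out["direction"] = np.where(out["rho_age"] > 0, "positive", "negative")
    return out


def differential_metabolites(matrix: pd.DataFrame, donors: pd.DataFrame) -> pd.DataFrame:
    """Per-ion Welch t-test old vs young, log2 fold change, Storey q."""
    donor_info = _match_donors(matrix, donors)
    groups = donor_info["group"].to_numpy()
    old = matrix.to_numpy(dtype=float)[:, groups == "old"]
    young = matrix.to_numpy(dtype=float)[:, groups == "young"]
    if old.shape[1] < 2 or young.shape[1] < 2:
        raise ValueError("each group needs at least 2 samples")
    res = sps.ttest_ind(old, young, axis=1, equal_var=False)
    log2fc = old.mean(axis=1) - young.mean(axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    defined = np.isfinite(p)
    if not defined.all():
        logger.warning("%d ions with undefined t-test excluded", int((~defined).sum()))
    q = np.full(len(matrix), np.nan)
    q[defined] = stats.storey_qvalues(p[defined])
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "t": np.asarray(res.statistic, dtype=float),
            "p": p,
            "q": q,
        },
        index=matrix.index,
    )


def significant_ions_differential(
    results: pd.DataFrame, fc_min: float = 0.1, q_max: float = 0.05
) -> pd.DataFrame:
    """Ions with |log2 fold change| strictly above fc_min and q below q_max."""
    keep = (results["log2fc"].abs() > fc_min) & (results["q"] < q_max)
    return results[keep].copy()
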