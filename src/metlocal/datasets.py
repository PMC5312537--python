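"""Bundled reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_reference_enzyme_stats"]


def load_reference_enzyme_stats() -> pd.DataFrame:
    """Published per-gene statistics for 21 metabolic enzymes whose
    expression changes with age in human epidermis and whose locality score
    is significant: locality score S and permutation p, Spearman gene-age
    correlation with p, and old-vs-young log2 fold change with BH-adjusted p.

    Serves as the reference surface for the locality hit filter: every row
    passes (p_locality < 0.05 and either p_age < 0.1 or adj_p < 0.1).
    """
    ref = resources.files("metlocal").joinpath("data/skin_aging_reference_hits.tsv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t").set_index("gene")
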