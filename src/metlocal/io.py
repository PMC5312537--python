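"""TSV readers and writers for all pipeline tables.

Matrices are features x samples with the feature id in the first column and
sample ids as header. Expression flags travel in the same file as companion
columns suffixed ``:flag``. Floats are written with a fixed general format so
reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

FLOAT_FMT = "%.10g"

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_expression",
    "write_expression",
    "read_ions",
    "write_ions",
    "read_donors",
    "read_metabolite_db",
    "read_network_edges",
    "write_network_edges",
    "read_enzyme_map",
    "write_enzyme_map",
    "read_pathways",
    "write_table",
]


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df


def write_matrix(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def write_expression(values: pd.DataFrame, flags: pd.DataFrame | None, path) -> None:
    out = values.copy()
    if flags is not None:
        flagged = flags.loc[values.index, values.columns]
        flagged.columns = [f"{c}:flag" for c in flagged.columns]
        out = pd.concat([out, flagged], axis=1)
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_expression(path) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    flag_cols = [c for c in df.columns if c.endswith(":flag")]
    value_cols = [c for c in df.columns if not c.endswith(":flag")]
    values = df[value_cols].astype(float)
    flags = None
    if flag_cols:
        flags = df[flag_cols]
        flags.columns = [c[: -len(":flag")] for c in flag_cols]
        flags = flags[value_cols]
    return values, flags


def write_ions(mz: pd.DataFrame, intensities: pd.DataFrame, path) -> None:
    out = pd.concat([mz["mz"], intensities], axis=1)
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_ions(path) -> tuple[pd.Series, pd.DataFrame]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "mz" not in df.columns:
        raise ValueError(f"{path}: expected an 'mz' column")
    return df["mz"].astype(float), df.drop(columns="mz").astype(float)


def read_donors(path) -> pd.DataFrame:
    donors = pd.read_csv(path, sep="\t")
    required = {"donor_id", "age", "group"}
    if not required <= set(donors.columns):
        raise ValueError(f"{path}: donor table needs columns {sorted(required)}")
    return donors


def read_metabolite_db(path) -> pd.DataFrame:
    db = pd.read_csv(path, sep="\t")
    required = {"compound_id", "mass"}
    if not required <= set(db.columns):
        raise ValueError(f"{path}: metabolite db needs columns {sorted(required)}")
    return db


def read_network_edges(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(df.itertuples(index=False, name=None))


def write_network_edges(edges, path) -> None:
    pd.DataFrame(edges, columns=["source", "target"]).to_csv(path, sep="\t", index=False)


def read_enzyme_map(path) -> dict[str, frozenset[str]]:
    df = pd.read_csv(path, sep="\t")
    return {
        row.gene: frozenset(str(row.compounds).split(","))
        for row in df.itertuples(index=False)
    }


def write_enzyme_map(enzyme_map: dict, path) -> None:
    rows = [
        {"gene": gene, "compounds": ",".join(sorted(mets))}
        for gene, mets in sorted(enzyme_map.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pathways(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"pathway_id", "member_id"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: pathway table needs columns {sorted(required)}")
    return df


def write_table(df: pd.DataFrame, path, index: bool = True) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)
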