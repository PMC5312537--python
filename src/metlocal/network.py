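"""Metabolite reaction-pair graph and enzyme-metabolite distances.

The metabolic model is an undirected graph whose nodes are metabolites and
whose edges are substrate-product pairs of enzymatic reactions; each enzyme
(gene) is incident to the metabolites of the reaction it catalyzes. The
network distance D between an enzyme and a metabolite is 1 + the shortest
path from the metabolite to the nearest incident metabolite, so incident
metabolites sit at D = 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MetabolicNetwork",
    "build_reaction_pair_graph",
    "enzyme_metabolite_distances",
    "map_ions_to_network",
]


@dataclass
class MetabolicNetwork:
    graph: nx.Graph
    enzyme_map: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        unknown = {
            enz: sorted(set(mets) - set(self.graph.nodes))
            for enz, mets in self.enzyme_map.items()
            if set(mets) - set(self.graph.nodes)
        }
        if unknown:
            raise ValueError(f"enzymes reference unknown compounds: {unknown}")
        empty = [enz for enz, mets in self.enzyme_map.items() if not mets]
        if empty:
            raise ValueError(f"enzymes with no incident metabolite: {empty}")


def build_reaction_pair_graph(
    edges, enzyme_map: dict[str, set[str] | frozenset[str]],
    extra_nodes=(),
) -> MetabolicNetwork:
    """Undirected simple graph from a compound-pair edge list.

    Duplicate and reversed edges collapse to one undirected edge; self-loops
    are rejected. `extra_nodes` admits isolated metabolites.
    """
    graph = nx.Graph()
    graph.add_nodes_from(extra_nodes)
    for u, v in edges:
        if u == v:
            raise ValueError(f"self-loop on {u}")
        graph.add_edge(u, v)
    return MetabolicNetwork(
        graph=graph, enzyme_map={e: frozenset(m) for e, m in enzyme_map.items()}
    )


def enzyme_metabolite_distances(
    network: MetabolicNetwork, measured_metabolites
) -> pd.DataFrame:
    """Distance matrix D (enzymes x measured metabolites).

    D[i, m] = 1 + shortest-path length from m to the nearest metabolite
    incident to enzyme i; unreachable entries are +inf (they carry zero
    weight downstream).
    """
    measured = [m for m in measured_metabolites if m in network.graph]
    missing = set(measured_metabolites) - set(measured)
    if missing:
        raise ValueError(f"measured metabolites absent from network: {sorted(missing)}")
    D = np.full((len(network.enzyme_map), len(measured)), np.inf)
    col = {m: j for j, m in enumerate(measured)}
    enzymes = sorted(network.enzyme_map)
    for i, enz in enumerate(enzymes):
        sources = list(network.enzyme_map[enz])
        lengths = nx.multi_source_dijkstra_path_length(
            network.graph, sources, weight=None
        )
        for m, dist in lengths.items():
            j = col.get(m)
            if j is not None:
                D[i, j] = 1.0 + dist
    return pd.DataFrame(D, index=pd.Index(enzymes, name="enzyme"), columns=measured)


def map_ions_to_network(
    annotations: pd.DataFrame,
    network: MetabolicNetwork,
    intensities: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse annotated ions to one intensity profile per network metabolite.

    When several ions annotate one metabolite, the ion with the smallest
    absolute mass error wins; when one ion annotates several metabolites it
    contributes to each, flagged ambiguous. Returns (metabolite x sample
    intensity table, mapping table with columns compound_id / ion_id /
    mass_error / ambiguous).
    """
    ann = annotations[annotations["compound_id"].isin(network.graph.nodes)].copy()
    if ann.empty:
        return (
            pd.DataFrame(columns=intensities.columns),
            pd.DataFrame(columns=["compound_id", "ion_id", "mass_error", "ambiguous"]),
        )
    ion_multiplicity = ann.groupby("ion_id")["compound_id"].transform("nunique")
    ann["ambiguous"] = ion_multiplicity > 1
    ann["abs_error"] = ann["mass_error"].abs()
    best = (
        ann.sort_values(["abs_error", "ion_id"], kind="mergesort")
        .groupby("compound_id", sort=True)
        .first()
        .reset_index()
    )
    profiles = intensities.loc[best["ion_id"]].to_numpy()
    table = pd.DataFrame(
        profiles, index=pd.Index(best["compound_id"], name="compound_id"),
        columns=intensities.columns,
    )
    mapping = best[["compound_id", "ion_id", "mass_error", "ambiguous"]]
    return table, mapping
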