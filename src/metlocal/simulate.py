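"""Synthetic matched-omics generator.

Emulates the structure of a two-age-group skin cohort measured on both a
flow-injection metabolomics platform and an expression microarray: a donor
table (young 20-25 y, old 55-66 y), a toy metabolite reaction-pair network
with enzyme incidences and monoisotopic masses, and matched expression /
ion-intensity matrices in which a chosen subset of enzymes carries a planted
group effect whose distance-1 metabolites co-vary with the enzyme's
expression. Every output is a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import networkx as nx
import numpy as np
import pandas as pd

from .network import MetabolicNetwork

PROTON_MASS = 1.007276
FLUORIDE_MASS = 18.998403

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_cohort",
    "generate_toy_network",
    "generate_matched_omics",
    "spike_artifacts",
    "gene_pathway_table",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort.

    Effect sizes are log2 units; coupling_strength is the target correlation
    magnitude between a planted enzyme's expression and its distance-1
    metabolites. Defaults mirror the matched 23+23 donor design.
    """

    n_young: int = 23
    n_old: int = 23
    age_range_young: tuple[int, int] = (20, 25)
    age_range_old: tuple[int, int] = (55, 66)
    n_ions: int = 150
    n_genes: int = 200
    n_metabolites: int = 120
    n_enzymes: int = 40
    n_planted_enzymes: int = 8
    effect_size_gene: float = 1.0
    coupling_strength: float = 0.8
    noise_sd: float = 0.2
    frac_saturated: float = 0.05
    frac_background: float = 0.05
    mass_tolerance: float = 0.001
    add_fluoride: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_young", "n_old", "n_ions", "n_genes", "n_metabolites",
                     "n_enzymes", "n_planted_enzymes"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_saturated", "frac_background"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must be in [0, 1]")
        ylo, yhi = self.age_range_young
        olo, ohi = self.age_range_old
        if not (ylo <= yhi < olo <= ohi):
            raise ValueError("age ranges must be disjoint with young below old")
        if self.n_planted_enzymes > self.n_enzymes:
            raise ValueError("cannot plant more enzymes than exist")
        if self.n_genes < self.n_enzymes:
            raise ValueError("n_genes must cover all enzyme genes")
        if self.n_ions < self.n_metabolites:
            raise ValueError("need at least one ion per metabolite")


@dataclass
class GroundTruth:
    """What was planted: the acceptance surface for locality recovery."""

    planted_enzymes: list[str]
    affected_metabolites: dict[str, list[str]] = field(default_factory=dict)
    gene_effect_sign: dict[str, int] = field(default_factory=dict)
    coupling_sign: dict[str, dict[str, int]] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _streams(config: SimulationConfig) -> dict[str, np.random.Generator]:
    """Named independent substreams so one stage's draws never shift another's."""
    root = np.random.SeedSequence(config.seed)
    names = ["cohort", "network", "omics", "artifacts"]
    children = root.spawn(len(names))
    return {name: np.random.default_rng(seq) for name, seq in zip(names, children)}


def generate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Donor table: one row per donor with integer age and group label."""
    rng = _streams(config)["cohort"]
    rows = []
    for group, n, (lo, hi) in (
        ("young", config.n_young, config.age_range_young),
        ("old", config.n_old, config.age_range_old),
    ):
        ages = rng.integers(lo, hi + 1, size=n)
        prefix = "Y" if group == "young" else "O"
        for i, age in enumerate(ages, start=1):
            rows.append({"donor_id": f"{prefix}{i:03d}", "age": int(age), "group": group})
    return pd.DataFrame(rows)


def _draw_masses(rng: np.random.Generator, n: int, tolerance: float,
                 guard_fluoride: bool) -> np.ndarray:
    """Unique monoisotopic masses in [80, 900] Da, pairwise separated by
    more than 3x the annotation tolerance so exact-mass annotation is
    unambiguous. With fluoride adducts enabled, also keeps every pair away
    from the [M-H]- / [M+F]- shift difference."""
    shift = PROTON_MASS + FLUORIDE_MASS  # mz collision offset between adducts
    masses: list[float] = []
    guard = 3.0 * tolerance
    attempts = 0
    while len(masses) < n:
        attempts += 1
        if attempts > 200 * n:
            raise ValueError("cannot place unique masses under the tolerance")
        m = float(rng.uniform(80.0, 900.0))
        ok = all(abs(m - other) > guard for other in masses)
        if ok and guard_fluoride:
            ok = all(abs(abs(m - other) - shift) > guard for other in masses)
        if ok:
            masses.append(m)
    return np.array(masses)


def generate_toy_network(config: SimulationConfig) -> tuple[MetabolicNetwork, pd.DataFrame]:
    """Connected toy reaction-pair network plus a compound database.

    The metabolite graph is a uniform random tree with ~10% extra edges;
    each enzyme is incident to 1-3 metabolites (the substrates/products of
    its reaction). Pathway labels partition metabolites into blocks of ~10.
    """
    if config.n_metabolites < 3:
        raise ValueError("need at least 3 metabolites")
    rng = _streams(config)["network"]
    n = config.n_metabolites
    mets = [f"C{i:04d}" for i in range(1, n + 1)]

    graph = nx.Graph()
    graph.add_nodes_from(mets)
    for j in range(1, n):  # random recursive tree: always connected
        graph.add_edge(mets[j], mets[int(rng.integers(0, j))])
    for _ in range(max(1, n // 10)):
        u, v = rng.choice(n, size=2, replace=False)
        graph.add_edge(mets[u], mets[v])

    enzyme_map: dict[str, frozenset[str]] = {}
    for e in range(1, config.n_enzymes + 1):
        k = int(rng.integers(1, 4))
        incident = rng.choice(n, size=k, replace=False)
        enzyme_map[f"ENZ{e:03d}"] = frozenset(mets[i] for i in incident)

    masses = _draw_masses(rng, n, config.mass_tolerance, config.add_fluoride)
    block = 10
    order = rng.permutation(n)
    pathway_of = {}
    for rank, idx in enumerate(order):
        pathway_of[mets[idx]] = f"MP{rank // block + 1:02d}"
    db = pd.DataFrame(
        {
            "compound_id": mets,
            "name": [f"metabolite_{m}" for m in mets],
            "mass": masses,
            "pathway": [pathway_of[m] for m in mets],
        }
    )
    return MetabolicNetwork(graph=graph, enzyme_map=enzyme_map), db


def gene_pathway_table(network: MetabolicNetwork, db: pd.DataFrame) -> pd.DataFrame:
    """Gene pathway memberships: an enzyme belongs to the pathways of its
    incident metabolites. Non-enzyme genes carry no metabolic pathway."""
    pathway_of = dict(zip(db["compound_id"], db["pathway"]))
    rows = []
    for enzyme, incident in network.enzyme_map.items():
        for pw in sorted({pathway_of[m] for m in incident}):
            rows.append({"pathway_id": f"GP_{pw}", "member_id": enzyme})
    return pd.DataFrame(rows, columns=["pathway_id", "member_id"])


def generate_matched_omics(
    cohort: pd.DataFrame,
    network: MetabolicNetwork,
    db: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Matched expression and ion-intensity matrices with planted effects.

    Returns (expression, ion_mz_table, ion_intensities, ground_truth).
    Expression is log2 scale, genes x donors; planted enzyme genes carry a
    +/- effect_size_gene old-vs-young contrast. Each planted enzyme's
    distance-1 metabolites track its standardized expression with
    correlation ~ coupling_strength (sign randomized per metabolite). Ion
    m/z are [M-H]- masses (optionally also [M+F]-) with uniform mass error
    within +/-0.0005 Da; intensities are 2**log2-abundance, so raw scale.
    """
    rng = _streams(config)["omics"]
    samples = cohort["donor_id"].tolist()
    n_s = len(samples)
    is_old = (cohort["group"] == "old").to_numpy()

    enzymes = sorted(network.enzyme_map)
    if config.n_planted_enzymes > len(enzymes):
        raise ValueError("planted count exceeds enzyme count")
    genes = enzymes + [f"GEN{i:03d}" for i in range(1, config.n_genes - len(enzymes) + 1)]
    planted = sorted(
        str(e) for e in rng.choice(enzymes, size=config.n_planted_enzymes, replace=False)
    )

    truth = GroundTruth(planted_enzymes=list(planted))
    baseline_g = rng.uniform(6.0, 12.0, size=len(genes))
    expr = baseline_g[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n_s))
    gene_index = {g: i for i, g in enumerate(genes)}
    for enz in planted:
        sign = int(rng.choice([-1, 1]))
        truth.gene_effect_sign[enz] = sign
        expr[gene_index[enz], is_old] += sign * config.effect_size_gene
    expression = pd.DataFrame(expr, index=pd.Index(genes, name="feature_id"), columns=samples)

    mets = db["compound_id"].tolist()
    met_index = {m: i for i, m in enumerate(mets)}
    baseline_m = rng.uniform(10.0, 16.0, size=len(mets))
    # independent unit-variance variation; planted metabolites get a mixture
    met_log = baseline_m[:, None] + rng.normal(0.0, 1.0, size=(len(mets), n_s))
    c = config.coupling_strength
    claimed: set[str] = set()
    for enz in planted:
        profile = expr[gene_index[enz]]
        z = (profile - profile.mean()) / profile.std()
        affected = sorted(network.enzyme_map[enz] - claimed)
        truth.affected_metabolites[enz] = affected
        truth.coupling_sign[enz] = {}
        for m in affected:
            claimed.add(m)
            sign = int(rng.choice([-1, 1]))
            truth.coupling_sign[enz][m] = sign
            eps = rng.normal(0.0, 1.0, size=n_s)
            met_log[met_index[m]] = baseline_m[met_index[m]] + sign * c * z + np.sqrt(
                max(0.0, 1.0 - c**2)
            ) * eps

    # ions: one [M-H]- ion per metabolite, plus unassignable noise ions
    ion_rows = []
    intens = []
    for m in mets:
        mz = db.loc[db["compound_id"] == m, "mass"].iloc[0] - PROTON_MASS
        mz += rng.uniform(-0.0005, 0.0005)
        ion_rows.append({"ion_id": f"ion{len(ion_rows) + 1:04d}", "mz": mz})
        intens.append(2.0 ** met_log[met_index[m]])
    if config.add_fluoride:
        extra = rng.choice(len(mets), size=max(1, len(mets) // 5), replace=False)
        for i in sorted(extra):
            mz = db["mass"].iloc[i] + FLUORIDE_MASS + rng.uniform(-0.0005, 0.0005)
            ion_rows.append({"ion_id": f"ion{len(ion_rows) + 1:04d}", "mz": mz})
            intens.append(2.0 ** (met_log[i] + rng.normal(0, 0.05, size=n_s)))
    adduct_mz = np.concatenate([db["mass"].to_numpy() - PROTON_MASS,
                                db["mass"].to_numpy() + FLUORIDE_MASS])
    while len(ion_rows) < config.n_ions:
        mz = float(rng.uniform(50.0, 1000.0))
        if np.min(np.abs(adduct_mz - mz)) <= 2 * config.mass_tolerance:
            continue
        ion_rows.append({"ion_id": f"ion{len(ion_rows) + 1:04d}", "mz": mz})
        intens.append(2.0 ** rng.normal(12.0, 1.0, size=n_s))

    ion_table = pd.DataFrame(ion_rows).set_index("ion_id")
    intensities = pd.DataFrame(
        np.vstack(intens), index=ion_table.index, columns=samples
    )
    return expression, ion_table, intensities, truth


def spike_artifacts(
    expression: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Per-cell QC flags ('ok' | 'saturated' | 'background').

    A fraction of features is spiked with each artifact class in a randomly
    chosen >=50% of samples, so the downstream QC filter (>=50% bad cells)
    removes exactly the spiked features.
    """
    rng = _streams(config)["artifacts"]
    n_feat, n_s = expression.shape
    flags = pd.DataFrame("ok", index=expression.index, columns=expression.columns)
    n_sat = int(round(config.frac_saturated * n_feat))
    n_bg = int(round(config.frac_background * n_feat))
    chosen = rng.choice(n_feat, size=min(n_feat, n_sat + n_bg), replace=False)
    for rank, feat_idx in enumerate(chosen):
        label = "saturated" if rank < n_sat else "background"
        n_bad = int(rng.integers((n_s + 1) // 2, n_s + 1))  # at least 50%
        cols = rng.choice(n_s, size=n_bad, replace=False)
        flags.iloc[feat_idx, cols] = label
    return flags
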