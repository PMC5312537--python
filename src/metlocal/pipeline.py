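"""End-to-end orchestration: simulate -> metabolomics -> transcriptomics ->
enrichment -> network locality -> hit filter, with one seed, logged filter
counts and byte-stable outputs."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io, metabolomics, stats, transcriptomics, enrichment, simulate as sim
from .network import build_reaction_pair_graph, enzyme_metabolite_distances, map_ions_to_network
from .locality import locality_analysis, filter_locality_hits

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "write_simulation", "run_pipeline", "report"]


@dataclass
class PipelineConfig:
    """All input paths and thresholds of a pipeline run.

    Threshold defaults are the published analysis settings: 0.001 Da
    annotation tolerance, |rho| > 0.25 & q < 0.01 for age-correlated ions,
    |log2FC| > 0.1 & q < 0.05 for differential ions, BH p < 0.01 &
    |log2FC| > 0.25 for transcripts, enrichment q < 0.01, locality p < 0.05
    with the age filter at p < 0.1, K = 10000 permutations, Storey
    lambda = 0.5.
    """

    ions: str = "ions.tsv"
    expression: str = "expression.tsv"
    donors: str = "donors.tsv"
    metabolite_db: str = "metabolite_db.tsv"
    network_edges: str = "network_edges.tsv"
    enzyme_map: str = "enzyme_map.tsv"
    pathways_metab: str = "pathways_metab.tsv"
    pathways_gene: str = "pathways_gene.tsv"

    tolerance: float = 0.001
    rho_min: float = 0.25
    q_corr: float = 0.01
    fc_min_metab: float = 0.1
    q_diff: float = 0.05
    fc_min_gene: float = 0.25
    adjp_gene: float = 0.01
    q_enrich: float = 0.01
    p_locality: float = 0.05
    p_age: float = 0.1
    adjp_hit: float = 0.1
    K: int = 10000
    storey_lambda: float = 0.5
    d_max: float = 0.0  # 0 = unbounded
    log_intensities: bool = True
    seed: int = 0

    thresholds: tuple = field(init=False, repr=False, default=())

    def __post_init__(self) -> None:
        for name in ("tolerance", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("q_corr", "q_diff", "adjp_gene", "q_enrich",
                     "p_locality", "p_age", "adjp_hit"):
            if not 0 < getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in (0, 1]")

    @classmethod
    def from_file(cls, path, **overrides) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        data.update({k: v for k, v in overrides.items() if v is not None})
        data.pop("thresholds", None)
        return cls(**data)


def write_simulation(config: sim.SimulationConfig, outdir) -> None:
    """Generate a full synthetic study and write every input table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort = sim.generate_cohort(config)
    network, db = sim.generate_toy_network(config)
    expr, ion_mz, intens, truth = sim.generate_matched_omics(cohort, network, db, config)
    flags = sim.spike_artifacts(expr, config)

    cohort.to_csv(outdir / "donors.tsv", sep="\t", index=False)
    io.write_expression(expr, flags, outdir / "expression.tsv")
    io.write_ions(ion_mz, intens, outdir / "ions.tsv")
    db.to_csv(outdir / "metabolite_db.tsv", sep="\t", index=False,
              float_format=io.FLOAT_FMT)
    io.write_network_edges(sorted(network.graph.edges), outdir / "network_edges.tsv")
    io.write_enzyme_map(network.enzyme_map, outdir / "enzyme_map.tsv")
    met_pw = db.rename(columns={"pathway": "pathway_id", "compound_id": "member_id"})
    io.write_table(met_pw[["pathway_id", "member_id"]].sort_values(
        ["pathway_id", "member_id"]), outdir / "pathways_metab.tsv", index=False)
    io.write_table(sim.gene_pathway_table(network, db),
                   outdir / "pathways_gene.tsv", index=False)
    truth.to_json(outdir / "ground_truth.json")
    logger.info("simulation written to %s", outdir)


def _ion_pathways(annotations: pd.DataFrame, met_pathways: pd.DataFrame) -> dict[str, set]:
    """Lift compound-level pathway definitions to the ion level: an ion
    belongs to a pathway iff any of its candidate compounds does."""
    merged = annotations.merge(
        met_pathways, left_on="compound_id", right_on="member_id"
    )
    return {pw: set(grp["ion_id"]) for pw, grp in merged.groupby("pathway_id")}


def run_pipeline(config: PipelineConfig, outdir) -> Path:
    """Execute every stage and write all result tables plus summary.json."""
    t0 = time.monotonic()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    d_max = config.d_max if config.d_max > 0 else None

    donors = io.read_donors(config.donors)
    ion_mz, raw_intens = io.read_ions(config.ions)
    expr_values, expr_flags = io.read_expression(config.expression)
    db = io.read_metabolite_db(config.metabolite_db)
    edges = io.read_network_edges(config.network_edges)
    enzyme_map = io.read_enzyme_map(config.enzyme_map)
    met_pathways = io.read_pathways(config.pathways_metab)
    gene_pathways = io.read_pathways(config.pathways_gene)

    for name, cols in (("ion matrix", raw_intens.columns),
                       ("expression matrix", expr_values.columns)):
        missing = set(cols) - set(donors["donor_id"])
        if missing:
            raise ValueError(f"{name} has samples absent from the donor table: "
                             f"{sorted(missing)}")

    # --- metabolome stage
    annotations = metabolomics.annotate_ions(ion_mz, db, tolerance=config.tolerance)
    norm_intens = metabolomics.normalize_intensities(
        raw_intens, log_transform=config.log_intensities)
    corr = metabolomics.correlate_with_age(norm_intens, donors)
    sig_corr = metabolomics.significant_ions_correlation(
        corr, rho_min=config.rho_min, q_max=config.q_corr)
    diff = metabolomics.differential_metabolites(norm_intens, donors)
    sig_diff = metabolomics.significant_ions_differential(
        diff, fc_min=config.fc_min_metab, q_max=config.q_diff)
    io.write_table(annotations, outdir / "annotations.tsv", index=False)
    io.write_table(corr, outdir / "metab_correlation.tsv")
    io.write_table(diff, outdir / "metab_differential.tsv")

    # --- transcriptome stage
    kept = transcriptomics.qc_filter_features(expr_values, expr_flags)
    kept_norm = stats.quantile_normalize(kept)
    gene_diff = transcriptomics.differential_expression(kept_norm, donors)
    sig_genes = transcriptomics.significant_transcripts(
        gene_diff, fc_min=config.fc_min_gene, p_max=config.adjp_gene)
    io.write_table(gene_diff, outdir / "gene_differential.tsv")

    # --- enrichment stage
    ranked_ions = sig_diff.sort_values(["q", "p"], kind="mergesort").index.tolist()
    ion_bg = diff.index[diff["q"].notna()]
    enr_met = enrichment.enrichment_fdr(
        enrichment.recursive_enrichment(
            ranked_ions, _ion_pathways(annotations, met_pathways), ion_bg),
        q_max=config.q_enrich)
    ranked_genes = sig_genes.sort_values("p", kind="mergesort").index.tolist()
    enr_gene = enrichment.enrichment_fdr(
        enrichment.recursive_enrichment(ranked_genes, gene_pathways, gene_diff.index),
        q_max=config.q_enrich)
    io.write_table(enr_met, outdir / "enrichment_metab.tsv")
    io.write_table(enr_gene, outdir / "enrichment_gene.tsv")

    # --- locality stage
    network = build_reaction_pair_graph(edges, enzyme_map, extra_nodes=db["compound_id"])
    met_levels, mapping = map_ions_to_network(annotations, network, norm_intens)
    distances = enzyme_metabolite_distances(network, met_levels.index)
    collapsed = transcriptomics.collapse_to_genes(kept_norm)
    loc = locality_analysis(
        collapsed, met_levels, distances, K=config.K,
        seed=np.random.default_rng(config.seed), d_max=d_max)
    companion = gene_diff.reindex(loc.index)[["rho_age", "p_age", "log2fc", "adj_p"]]
    loc = pd.concat([loc, companion], axis=1)
    hits = filter_locality_hits(
        loc, p_locality_max=config.p_locality,
        p_age_max=config.p_age, adj_p_max=config.adjp_hit)
    io.write_table(mapping, outdir / "ion_metabolite_map.tsv", index=False)
    io.write_table(loc, outdir / "locality_scores.tsv")
    io.write_table(hits, outdir / "locality_hits.tsv")

    summary = {
        "counts": {
            "ions_detected": int(len(ion_mz)),
            "ions_annotated": int(annotations["ion_id"].nunique()),
            "ions_correlation_significant": int(len(sig_corr)),
            "ions_correlation_positive": int((sig_corr["direction"] == "positive").sum()),
            "ions_correlation_negative": int((sig_corr["direction"] == "negative").sum()),
            "ions_differential_significant": int(len(sig_diff)),
            "features_input": int(len(expr_values)),
            "features_retained": int(len(kept)),
            "transcripts_significant": int(len(sig_genes)),
            "transcripts_up": int((sig_genes["direction"] == "up").sum()),
            "transcripts_down": int((sig_genes["direction"] == "down").sum()),
            "pathways_metab_significant": int(enr_met["significant"].sum()),
            "pathways_gene_significant": int(enr_gene["significant"].sum()),
            "network_metabolites_measured": int(len(met_levels)),
            "enzymes_scored": int(len(loc)),
            "locality_significant": int((loc["p_locality"] < config.p_locality).sum()),
            "locality_hits": int(len(hits)),
        },
        "thresholds": {
            k: v for k, v in asdict(config).items()
            if k not in {"ions", "expression", "donors", "metabolite_db",
                         "network_edges", "enzyme_map", "pathways_metab",
                         "pathways_gene", "thresholds"}
        },
        "seed": config.seed,
    }
    truth_path = Path(config.ions).parent / "ground_truth.json"
    if truth_path.exists():
        truth = sim.GroundTruth.from_json(truth_path)
        planted = [e for e in truth.planted_enzymes if e in loc.index]
        recovered = [e for e in planted
                     if loc.loc[e, "p_locality"] < config.p_locality]
        summary["planted_recovery"] = {
            "planted": len(truth.planted_enzymes),
            "scored": len(planted),
            "recovered": len(recovered),
        }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline finished in %.1f s", time.monotonic() - t0)
    return outdir


def report(run_dir) -> str:
    """Human-readable summary of a completed run."""
    run_dir = Path(run_dir)
    summary_path = run_dir / "summary.json"
    if not summary_path.exists():
        raise FileNotFoundError(f"no summary.json in {run_dir}; incomplete run?")
    summary = json.loads(summary_path.read_text())
    lines = ["run summary", "-----------"]
    for key, value in sorted(summary["counts"].items()):
        lines.append(f"{key:38s} {value}")
    if "planted_recovery" in summary:
        pr = summary["planted_recovery"]
        lines.append(f"{'planted enzymes recovered':38s} {pr['recovered']}/{pr['planted']}")
    hits_path = run_dir / "locality_hits.tsv"
    if hits_path.exists():
        hits = pd.read_csv(hits_path, sep="\t", index_col=0)
        if len(hits):
            lines.append("")
            lines.append("locality hits (gene, S, p, rho_age, p_age, log2fc, adj_p):")
            for gene, row in hits.iterrows():
                lines.append(
                    f"  {gene:12s} {row['S']:.2f} {row['p_locality']:.3g} "
                    f"{row['rho_age']:+.2f} {row['p_age']:.3g} "
                    f"{row['log2fc']:+.2f} {row['adj_p']:.3g}"
                )
    else:
        lines.append("warning: locality_hits.tsv missing (partial run)")
    return "\n".join(lines)
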