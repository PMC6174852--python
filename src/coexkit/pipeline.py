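"""End-to-end workflow wiring: DGE -> set algebra -> co-expression ->
enrichment -> paired-mutant categorization, with a reproducibility manifest.

The run either loads a fixture bundle from disk or generates the default
synthetic compendium, then emits every stage's tables under one output
directory together with a JSON manifest recording thresholds, the
enrichment universe policy, and SHA-256 checksums of all outputs; a rerun
with the same seed reproduces the checksums bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .categories import category_overlap_tests, classify_all
from .coexpression import (
    correlation_matrix,
    exclusive_intersections,
    filter_expressed,
    hierarchical_order,
    partner_set,
    tissue_dendrogram,
    tissue_mean_profiles,
)
from .containers import CountMatrix, GeneSet
from .dge import compute_rpkm, effective_library_sizes, estimate_common_dispersion, run_dge, select_enriched, tmm_factors
from .io import (
    read_count_matrix,
    write_dge_result,
    write_enrichment_results,
    write_gene_sets_gmt,
    write_intersections,
)
from .simulate import SimConfig, Truth, simulate_mutant_experiment, simulate_tissue_experiment

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths, thresholds and policies for one pipeline run.

    When the count paths are None the synthetic compendium (tissue +
    paired-mutant designs) is generated from ``sim`` / ``seed``.
    """

    outdir: str | Path = "coexkit_run"
    counts_path: str | None = None
    sample_map_path: str | None = None
    gene_lengths_path: str | None = None
    mutant_counts_path: str | None = None
    mutant_sample_map_path: str | None = None
    sim: SimConfig | None = None
    # thresholds (strict inequalities everywhere)
    p_max: float = 0.01
    r_min: float = 0.8
    corr_p_max: float = 0.001
    rpkm_floor: float = 5.0
    logfc_floor: float = 0.0
    logcpm_floor: float = 0.0
    phi: float | None = None
    universe_policy: str = "expressed"  # or "all"
    reference_tissue: str | None = None
    max_matrix_genes: int = 1500
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1 and 0 < self.corr_p_max <= 1):
            raise ValueError("p thresholds must lie in (0, 1]")
        if not (-1 <= self.r_min <= 1):
            raise ValueError("r_min must lie in [-1, 1]")
        if self.rpkm_floor < 0:
            raise ValueError("rpkm_floor must be >= 0")
        if self.universe_policy not in ("expressed", "all"):
            raise ValueError(f"unknown universe policy {self.universe_policy!r}")
        for p in (self.counts_path, self.sample_map_path, self.gene_lengths_path,
                  self.mutant_counts_path, self.mutant_sample_map_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written to disk)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage = "setup"
    timings: dict[str, float] = {}

    def emit(name: str, path: Path) -> Path:
        outputs[name] = path
        return path

    try:
        # ------------------------------------------------------------- data
        stage = "load_data"
        t0 = time.perf_counter()
        truth: Truth | None = None
        mutant_truth: Truth | None = None
        if config.counts_path is not None:
            cm = read_count_matrix(config.counts_path, config.sample_map_path, config.gene_lengths_path)
        else:
            sim = config.sim or SimConfig(seed=config.seed)
            cm, truth = simulate_tissue_experiment(sim)
        if config.mutant_counts_path is not None:
            mut = read_count_matrix(config.mutant_counts_path, config.mutant_sample_map_path, config.gene_lengths_path)
        elif config.counts_path is None:
            sim = config.sim or SimConfig(seed=config.seed)
            mut, mutant_truth = simulate_mutant_experiment(sim)
        else:
            mut = None
        timings[stage] = time.perf_counter() - t0

        # -------------------------------------------------------------- dge
        stage = "dge"
        t0 = time.perf_counter()
        tissues = cm.group_labels(by="tissue")
        reference = config.reference_tissue or ("thallus" if "thallus" in tissues else tissues[0])
        phi = config.phi
        if phi is None:
            phi = estimate_common_dispersion(cm, by="tissue")
        logger.info("common dispersion phi=%.4g; reference tissue %r", phi, reference)
        up_sets: list[GeneSet] = []
        dge_results = {}
        for tissue in tissues:
            if tissue == reference:
                continue
            result = run_dge(cm, contrast=(reference, tissue), phi=phi)
            dge_results[tissue] = result
            write_dge_result(result, emit(f"dge_{tissue}", outdir / f"dge_{tissue}.tsv"))
            up_sets.append(
                select_enriched(
                    result,
                    p_max=config.p_max,
                    min_logfc=config.logfc_floor,
                    min_logcpm=config.logcpm_floor,
                    direction="up",
                    name=tissue,
                )
            )
        write_gene_sets_gmt(up_sets, emit("tissue_up_sets", outdir / "tissue_up_sets.gmt"))
        timings[stage] = time.perf_counter() - t0

        # ------------------------------------------------------- intersect
        stage = "intersect"
        t0 = time.perf_counter()
        if up_sets:
            inter = exclusive_intersections(up_sets)
            write_intersections(inter, [s.name for s in up_sets], emit("intersections", outdir / "intersections.tsv"))
        timings[stage] = time.perf_counter() - t0

        # ------------------------------------------------------ coexpress
        stage = "coexpress"
        t0 = time.perf_counter()
        factors = tmm_factors(cm)
        eff = effective_library_sizes(cm, factors)
        rpkm = compute_rpkm(cm, eff)
        profiles = tissue_mean_profiles(rpkm, cm.sample_map)
        retained = filter_expressed(profiles, min_rpkm=config.rpkm_floor)
        retained.values.to_csv(emit("tissue_profiles", outdir / "tissue_profiles.tsv"), sep="\t", index_label="gene")

        seeds: list[str] = []
        if truth is not None:
            for m in sorted(truth.module_membership.dropna().unique()):
                members = truth.module_genes(int(m))
                in_profiles = [g for g in members if g in retained.genes]
                if in_profiles:
                    seeds.append(in_profiles[0])
            if truth.regulator is not None and truth.regulator in retained.genes:
                seeds.append(truth.regulator)
        else:
            order = retained.values.var(axis=1).sort_values(ascending=False)
            seeds = list(order.index[: min(5, len(order))])

        group_rows = []
        groups = {}
        for seed_gene in seeds:
            group = partner_set(retained, seed_gene, r_min=config.r_min, p_max=config.corr_p_max)
            groups[seed_gene] = group
            for gene, row in group.partners.iterrows():
                group_rows.append(
                    {"seed": seed_gene, "partner": gene, "r": row["r"], "pvalue": row["pvalue"],
                     "mean_coefficient": group.mean_coefficient}
                )
        pd.DataFrame(group_rows, columns=["seed", "partner", "r", "pvalue", "mean_coefficient"]).to_csv(
            emit("coexpression_groups", outdir / "coexpression_groups.tsv"), sep="\t", index=False
        )

        matrix_genes = retained.genes
        if len(matrix_genes) > config.max_matrix_genes:
            by_var = retained.values.var(axis=1).sort_values(ascending=False)
            matrix_genes = by_var.index[: config.max_matrix_genes]
        sub = filter_expressed(profiles, min_rpkm=config.rpkm_floor)
        sub.values = sub.values.loc[matrix_genes]
        corr = correlation_matrix(sub)
        gene_tree = hierarchical_order(corr.r)
        (outdir / "gene_order.newick").write_text(gene_tree.to_newick() + "\n")
        emit("gene_order", outdir / "gene_order.newick")
        tree = tissue_dendrogram(retained)
        (outdir / "tissue_dendrogram.newick").write_text(tree.to_newick() + "\n")
        emit("tissue_dendrogram", outdir / "tissue_dendrogram.newick")
        timings[stage] = time.perf_counter() - t0

        # --------------------------------------------------------- enrich
        stage = "enrich"
        t0 = time.perf_counter()
        if config.universe_policy == "expressed":
            universe = GeneSet("expressed", retained.genes, provenance=f"max tissue-mean RPKM > {config.rpkm_floor}")
        else:
            universe = GeneSet("all_genes", cm.genes, provenance="all genes in the count matrix")
        from .enrichment import fisher_enrichment

        enrich_results = []
        for seed_gene, group in groups.items():
            query = group.to_gene_set()
            for tissue_set in up_sets:
                enrich_results.append(fisher_enrichment(query, tissue_set, universe))
        write_enrichment_results(enrich_results, emit("coexpression_enrichment", outdir / "coexpression_enrichment.tsv"))
        timings[stage] = time.perf_counter() - t0

        # ----------------------------------------------------- categorize
        stage = "categorize"
        t0 = time.perf_counter()
        categories = None
        if mut is not None:
            genotypes = mut.group_labels(by="genotype")
            wild = "wild_type" if "wild_type" in genotypes else genotypes[0]
            others = [g for g in genotypes if g != wild]
            lof = next((g for g in others if "loss" in g), others[0])
            gof = next((g for g in others if g != lof), others[-1])
            mut_phi = config.phi
            if mut_phi is None:
                mut_phi = estimate_common_dispersion(mut, by="genotype")
            dge_lof = run_dge(mut, contrast=(wild, lof), by="genotype", phi=mut_phi)
            dge_gof = run_dge(mut, contrast=(wild, gof), by="genotype", phi=mut_phi)
            write_dge_result(dge_lof, emit("dge_lof", outdir / "dge_lof.tsv"))
            write_dge_result(dge_gof, emit("dge_gof", outdir / "dge_gof.tsv"))
            categories = classify_all(dge_lof, dge_gof, p_max=config.p_max)
            categories.table.to_csv(emit("categories", outdir / "categories.tsv"), sep="\t", index_label="gene")
            cat_universe = GeneSet("tested", categories.table.index, provenance="genes tested in both mutant contrasts")
            overlap = category_overlap_tests(categories, up_sets, cat_universe)
            write_enrichment_results(overlap, emit("category_enrichment", outdir / "category_enrichment.tsv"))
        timings[stage] = time.perf_counter() - t0

        # ------------------------------------------------------- manifest
        stage = "manifest"
        sim_used = (config.sim or SimConfig(seed=config.seed)) if config.counts_path is None else None
        manifest = {
            "coexkit_version": __version__,
            "seed": config.seed,
            "thresholds": {
                "p_max": config.p_max,
                "r_min": config.r_min,
                "corr_p_max": config.corr_p_max,
                "rpkm_floor": config.rpkm_floor,
                "logfc_floor": config.logfc_floor,
                "logcpm_floor": config.logcpm_floor,
            },
            "dispersion": phi,
            "universe_policy": config.universe_policy,
            "universe_size": len(universe),
            "reference_tissue": reference,
            "sim_config": asdict(sim_used) if sim_used is not None else None,
            "timings_s": {k: round(v, 3) for k, v in timings.items()},
            "outputs": {name: {"path": str(p.name), "sha256": _sha256(p)} for name, p in outputs.items()},
        }
        manifest_path = outdir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
        return manifest
    except PipelineError:
        raise
    except Exception as exc:  # annotate with the failing stage
        raise PipelineError(stage, exc) from exc
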