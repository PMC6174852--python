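"""Synthetic count-matrix generator with planted, recoverable structure.

Emulates a multi-tissue bulk RNA-seq compendium: ~11 tissue groups with
2-3 replicates each, negative-binomial counts (variance mu + phi*mu^2)
around tissue-archetype means scaled by log-normal library sizes.  Planted
structure -- co-expressed gene modules sharing a tissue archetype,
tissue-enriched genes with a fixed log2 effect, and a regulator with
activated/repressed target sets realized across paired wild-type /
loss-of-function / derepressed genotypes -- is recorded in a Truth object
so every downstream stage can be scored against ground truth.

Gene indices are allocated deterministically (modules first, then one
planted-enriched block per tissue, then mutant target blocks), and the
repressed-target block coincides with the reproductive-tissue enriched
block: the planted regulator represses reproductive-program genes, the
structure the paired-mutant categorization is designed to recover.

Two RNG streams are derived from the seed: a structure stream (archetypes,
baselines, lengths) and a noise stream (library sizes, counts), so
changing the replicate count never reshuffles the planted structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix

DEFAULT_TISSUES = [
    "sporeling_24h",
    "archegoniophore",
    "sporeling_48h",
    "sporeling_72h",
    "sporeling_96h",
    "thallus",
    "apical_cell",
    "antheridiophore",
    "antheridia",
    "sporophyte_13d",
    "sporophyte_mature",
]

REPRODUCTIVE_TISSUE = "archegoniophore"
GENOTYPES = ("wild_type", "loss_of_function", "derepressed")


class SimConfigError(ValueError):
    pass


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic compendium.

    Defaults reproduce the scale of the emulated design: 16520 genes over
    11 tissues in triplicate, ~1e7 reads per library, common dispersion
    0.1, nine 30-gene co-expressed modules, and regulator target-set sizes
    (112, 115, 501, 470) for (activated, repressed, secondary-up,
    secondary-down).
    """

    n_genes: int = 16520
    tissues: list[str] = field(default_factory=lambda: list(DEFAULT_TISSUES))
    replicates_per_tissue: int = 3
    library_size_mean: float = 1e7
    library_size_cv: float = 0.3
    dispersion: float = 0.1
    n_modules: int = 9
    module_size: int = 30
    module_profile_sd: float = 2.0
    n_planted_de_per_tissue: int = 50
    planted_log2fc: float = 2.0
    regulator_targets: tuple[int, int, int, int] = (112, 115, 501, 470)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.replicates_per_tissue <= 0:
            raise SimConfigError("n_genes and replicates_per_tissue must be positive")
        if not self.tissues:
            raise SimConfigError("need at least one tissue")
        if len(set(self.tissues)) != len(self.tissues):
            raise SimConfigError("tissue labels must be unique")
        if self.dispersion < 0:
            raise SimConfigError("dispersion must be >= 0")
        if self.library_size_mean <= 0:
            raise SimConfigError("library_size_mean must be positive")
        if self.n_modules < 0 or self.module_size < 0 or self.n_planted_de_per_tissue < 0:
            raise SimConfigError("structure sizes must be >= 0")
        if self.n_modules * self.module_size > self.n_genes:
            raise SimConfigError("module_size * n_modules exceeds n_genes")
        if any(x < 0 for x in self.regulator_targets):
            raise SimConfigError("regulator target sizes must be >= 0")
        needed = self._allocation_end()
        if needed > self.n_genes:
            raise SimConfigError(
                f"planted structure needs {needed} genes but n_genes={self.n_genes}"
            )

    @classmethod
    def scaled(cls, n_genes: int, seed: int = 0, **overrides) -> "SimConfig":
        """A design scaled down (or up) to *n_genes*, planted structure
        shrunk proportionally with sensible floors."""
        f = n_genes / cls.__dataclass_fields__["n_genes"].default
        t1, t2, t3, t4 = (112, 115, 501, 470)
        params = dict(
            n_genes=n_genes,
            seed=seed,
            n_modules=max(2, round(9 * f)),
            module_size=max(10, round(30 * f)),
            n_planted_de_per_tissue=max(5, round(50 * f)),
            regulator_targets=tuple(max(5, round(t * f)) for t in (t1, t2, t3, t4)),
        )
        params.update(overrides)
        return cls(**params)

    # -- deterministic index allocation shared by both designs -------------
    @property
    def module_block_end(self) -> int:
        return self.n_modules * self.module_size

    def tissue_block(self, tissue_index: int) -> range:
        start = self.module_block_end + tissue_index * self.n_planted_de_per_tissue
        return range(start, start + self.n_planted_de_per_tissue)

    @property
    def free_start(self) -> int:
        return self.module_block_end + len(self.tissues) * self.n_planted_de_per_tissue

    def category_indices(self) -> dict[int, np.ndarray]:
        """Gene indices for categories 1-4 (activated, repressed, 2x secondary).

        Repressed targets (category 2) occupy the reproductive tissue's
        planted-enriched block first, spilling into the free region.
        """
        n_act, n_rep, n_up, n_down = self.regulator_targets
        repro = (
            self.tissues.index(REPRODUCTIVE_TISSUE)
            if REPRODUCTIVE_TISSUE in self.tissues
            else min(1, len(self.tissues) - 1)
        )
        block = list(self.tissue_block(repro))
        cat2 = block[: min(n_rep, len(block))]
        cursor = self.free_start
        cat1 = list(range(cursor, cursor + n_act))
        cursor += n_act
        spill = n_rep - len(cat2)
        cat2 = cat2 + list(range(cursor, cursor + spill))
        cursor += spill
        cat3 = list(range(cursor, cursor + n_up))
        cursor += n_up
        cat4 = list(range(cursor, cursor + n_down))
        return {
            1: np.array(cat1, dtype=int),
            2: np.array(cat2, dtype=int),
            3: np.array(cat3, dtype=int),
            4: np.array(cat4, dtype=int),
        }

    def _allocation_end(self) -> int:
        n_act, n_rep, n_up, n_down = self.regulator_targets
        spill = max(0, n_rep - self.n_planted_de_per_tissue)
        return self.free_start + n_act + spill + n_up + n_down

    def gene_ids(self) -> pd.Index:
        width = max(5, len(str(self.n_genes)))
        return pd.Index([f"g{i:0{width}d}" for i in range(self.n_genes)], name="gene")


@dataclass
class Truth:
    """Ground-truth labels for one simulated design."""

    module_membership: pd.Series  # Int64, <NA> for unplanted genes
    tissue_enriched: pd.DataFrame  # index gene; columns tissue, log2fc
    category_label: pd.Series  # int, 0 = none
    gene_lengths: pd.Series
    regulator: str | None = None

    def module_genes(self, module: int) -> list[str]:
        mask = self.module_membership == module
        return list(self.module_membership.index[mask.fillna(False)])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(index=self.module_membership.index)
        frame["module"] = self.module_membership
        frame["enriched_tissue"] = self.tissue_enriched["tissue"].reindex(frame.index)
        frame["enriched_log2fc"] = self.tissue_enriched["log2fc"].reindex(frame.index)
        frame["category"] = self.category_label
        frame["length_bp"] = self.gene_lengths
        return frame


def _streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    structure, noise = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(structure), np.random.default_rng(noise)


def nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws with variance mean + dispersion*mean^2 (gamma-Poisson mixture)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / dispersion, scale=dispersion * mean)
    return rng.poisson(lam)


def _gene_lengths(rng: np.random.Generator, n_genes: int) -> np.ndarray:
    lengths = np.round(rng.lognormal(mean=np.log(1500.0), sigma=0.5, size=n_genes))
    return np.maximum(lengths, 200.0)


def _baselines(rng: np.random.Generator, cfg: SimConfig, planted: np.ndarray) -> np.ndarray:
    """Relative abundance weights on log2 scale; planted genes drawn from
    the upper (reliably detectable) expression range, as study-identified
    modules and targets are by construction expressed genes."""
    log2_b = rng.normal(loc=0.0, scale=2.0, size=cfg.n_genes)
    log2_b[planted] = rng.normal(loc=2.0, scale=1.0, size=int(planted.sum()))
    return 2.0**log2_b


def _library_sizes(rng: np.random.Generator, cfg: SimConfig, n: int) -> np.ndarray:
    cv = max(cfg.library_size_cv, 1e-12)
    sigma = np.sqrt(np.log1p(cv**2))
    mu = np.log(cfg.library_size_mean) - sigma**2 / 2.0
    return rng.lognormal(mean=mu, sigma=sigma, size=n)


def simulate_tissue_experiment(config: SimConfig) -> tuple[CountMatrix, Truth]:
    """Multi-tissue design with planted modules and tissue-enriched genes."""
    cfg = config
    structure, noise = _streams(cfg.seed)
    genes = cfg.gene_ids()
    n_tissues = len(cfg.tissues)

    planted = np.zeros(cfg.n_genes, dtype=bool)
    planted[: cfg.free_start] = True
    lengths = _gene_lengths(structure, cfg.n_genes)
    baselines = _baselines(structure, cfg, planted)

    # log2 tissue profile: module genes share their module's archetype,
    # background genes get a mild private profile, planted-enriched genes a
    # +planted_log2fc bump in their tissue.
    profile = structure.normal(loc=0.0, scale=0.3, size=(cfg.n_genes, n_tissues))
    module_id = pd.array([pd.NA] * cfg.n_genes, dtype="Int64")
    # each module is anchored to its own peak tissue (round-robin), on top
    # of a random archetype: co-expression groups in multi-tissue compendia
    # are largely tissue-specific, and anchoring keeps modules mutually
    # distinguishable
    archetypes = structure.normal(loc=0.0, scale=cfg.module_profile_sd, size=(cfg.n_modules, n_tissues))
    for m in range(cfg.n_modules):
        archetypes[m, m % n_tissues] += 2.0 * cfg.module_profile_sd
    for m in range(cfg.n_modules):
        rows = slice(m * cfg.module_size, (m + 1) * cfg.module_size)
        profile[rows] = archetypes[m]
        module_id[rows] = m
    enr_rows: list[tuple[str, str, float]] = []
    for j, tissue in enumerate(cfg.tissues):
        idx = np.fromiter(cfg.tissue_block(j), dtype=int)
        profile[idx, j] += cfg.planted_log2fc
        enr_rows.extend((genes[i], tissue, cfg.planted_log2fc) for i in idx)

    mean_weight = baselines[:, None] * 2.0**profile  # genes x tissues
    rel = mean_weight / mean_weight.sum(axis=0)

    samples, tissue_of = [], []
    for tissue in cfg.tissues:
        for r in range(1, cfg.replicates_per_tissue + 1):
            samples.append(f"{tissue}_r{r}")
            tissue_of.append(tissue)
    libs = _library_sizes(noise, cfg, len(samples))
    counts = np.empty((cfg.n_genes, len(samples)), dtype=np.int64)
    for s, tissue in enumerate(tissue_of):
        j = cfg.tissues.index(tissue)
        counts[:, s] = nb_counts(noise, rel[:, j] * libs[s], cfg.dispersion)

    sample_map = pd.DataFrame(
        {
            "tissue": tissue_of,
            "genotype": "wild_type",
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        sample_map=sample_map,
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
    )
    enriched = pd.DataFrame(enr_rows, columns=["gene", "tissue", "log2fc"]).set_index("gene")
    repro = REPRODUCTIVE_TISSUE if REPRODUCTIVE_TISSUE in cfg.tissues else cfg.tissues[min(1, n_tissues - 1)]
    repro_block = cfg.tissue_block(cfg.tissues.index(repro))
    regulator = genes[repro_block.start] if len(repro_block) else None
    truth = Truth(
        module_membership=pd.Series(module_id, index=genes, name="module"),
        tissue_enriched=enriched,
        category_label=pd.Series(0, index=genes, name="category"),
        gene_lengths=cm.gene_lengths,
        regulator=regulator,
    )
    return cm, truth


def simulate_mutant_experiment(config: SimConfig) -> tuple[CountMatrix, Truth]:
    """Paired-mutant design: wild type, loss-of-function, derepressed.

    Activated targets (category 1) shift down in the loss-of-function and
    up in the derepressed genotype; repressed targets (category 2) the
    converse; secondary genes (3/4) shift the same direction in both.
    """
    cfg = config
    structure, noise = _streams(cfg.seed)
    genes = cfg.gene_ids()
    cats = cfg.category_indices()

    planted = np.zeros(cfg.n_genes, dtype=bool)
    planted[: cfg.free_start] = True
    for idx in cats.values():
        planted[idx] = True
    lengths = _gene_lengths(structure, cfg.n_genes)
    # burn the tissue-design structure draws so the two designs stay
    # aligned on gene identity regardless of which is generated
    baselines = _baselines(structure, cfg, planted)

    lfc = cfg.planted_log2fc
    # per-genotype log2 shift for each category: (lof, derepressed)
    shifts = {1: (-lfc, +lfc), 2: (+lfc, -lfc), 3: (+lfc, +lfc), 4: (-lfc, -lfc)}
    log2_shift = np.zeros((cfg.n_genes, len(GENOTYPES)))
    for cat, idx in cats.items():
        lof_shift, gof_shift = shifts[cat]
        log2_shift[idx, 1] = lof_shift
        log2_shift[idx, 2] = gof_shift

    mean_weight = baselines[:, None] * 2.0**log2_shift
    rel = mean_weight / mean_weight.sum(axis=0)

    samples, genotype_of = [], []
    for genotype in GENOTYPES:
        for r in range(1, cfg.replicates_per_tissue + 1):
            samples.append(f"{genotype}_r{r}")
            genotype_of.append(genotype)
    libs = _library_sizes(noise, cfg, len(samples))
    counts = np.empty((cfg.n_genes, len(samples)), dtype=np.int64)
    for s, genotype in enumerate(genotype_of):
        j = GENOTYPES.index(genotype)
        counts[:, s] = nb_counts(noise, rel[:, j] * libs[s], cfg.dispersion)

    sample_map = pd.DataFrame(
        {
            "tissue": "thallus",
            "genotype": genotype_of,
            "replicate": [int(s.rsplit("_r", 1)[1]) for s in samples],
        },
        index=pd.Index(samples, name="sample"),
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        sample_map=sample_map,
        gene_lengths=pd.Series(lengths, index=genes, name="length_bp"),
    )
    category = pd.Series(0, index=genes, name="category")
    for cat, idx in cats.items():
        category.iloc[idx] = cat
    truth = Truth(
        module_membership=pd.Series(pd.array([pd.NA] * cfg.n_genes, dtype="Int64"), index=genes),
        tissue_enriched=pd.DataFrame(columns=["tissue", "log2fc"]),
        category_label=category,
        gene_lengths=cm.gene_lengths,
    )
    return cm, truth


def write_fixture_bundle(counts: CountMatrix, truth: Truth, outdir: str | Path) -> dict[str, Path]:
    """Write the standard TSV bundle: counts, sample map, lengths, truth."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": outdir / "counts.tsv",
        "sample_map": outdir / "sample_map.tsv",
        "gene_lengths": outdir / "gene_lengths.tsv",
        "truth": outdir / "truth.tsv",
    }
    counts.counts.to_csv(paths["counts"], sep="\t", index_label="gene")
    counts.sample_map.to_csv(paths["sample_map"], sep="\t", index_label="sample")
    counts.gene_lengths.rename("length_bp").to_csv(paths["gene_lengths"], sep="\t", index_label="gene")
    truth.to_frame().to_csv(paths["truth"], sep="\t", index_label="gene")
    return paths
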