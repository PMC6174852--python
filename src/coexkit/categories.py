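"""Regulatory categorization from paired loss/gain-of-function contrasts.

A regulator assayed with both a loss-of-function mutant and a derepressed
(gain) mutant lets converse expression shifts separate its dependent genes
from secondary feedback:

* Category 1 (regulator-activated): down in the loss-of-function contrast
  and up in the derepressed contrast.
* Category 2 (regulator-repressed): the converse sign pattern.
* Category 3 / 4: up in both / down in both -- secondary effects moving
  with, not against, the mutant backgrounds.

Both contrasts must be significant at the gate (raw p < 0.01 by default)
for any call; everything else is "none".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneSet
from .dge import DGEResult
from .enrichment import EnrichmentResult, fisher_enrichment


class CategoryError(ValueError):
    pass


CATEGORY_NONE = 0  # stored as integer 0 to keep the table dense


@dataclass
class CategoryTable:
    """Per-gene category call (1-4, 0 = none) with source statistics."""

    table: pd.DataFrame  # index gene; category, lfc_lof, p_lof, lfc_gof, p_gof, engines
    contrast_lof: tuple[str, str]
    contrast_gof: tuple[str, str]
    p_max: float = 0.01

    def gene_set(self, category: int, name: str | None = None) -> GeneSet:
        members = self.table.index[self.table["category"] == category]
        return GeneSet(
            name=name or f"category_{category}",
            members=frozenset(members),
            provenance=f"category {category} at p<{self.p_max} "
            f"(lof {self.contrast_lof}, gof {self.contrast_gof})",
        )

    def counts(self) -> dict[int, int]:
        vc = self.table["category"].value_counts()
        return {c: int(vc.get(c, 0)) for c in (1, 2, 3, 4)}


def classify_gene(
    lfc_lof: float,
    p_lof: float,
    lfc_gof: float,
    p_gof: float,
    p_max: float = 0.01,
) -> int:
    """Category from the sign pattern of two significant contrasts.

    (-,+) -> 1, (+,-) -> 2, (+,+) -> 3, (-,-) -> 4; 0 (none) unless both
    p-values clear the gate.  A logFC of exactly 0 in either contrast has
    no sign pattern and yields none.
    """
    if not (np.isfinite(lfc_lof) and np.isfinite(lfc_gof) and np.isfinite(p_lof) and np.isfinite(p_gof)):
        return CATEGORY_NONE
    if not (p_lof < p_max and p_gof < p_max):
        return CATEGORY_NONE
    if lfc_lof == 0.0 or lfc_gof == 0.0:
        return CATEGORY_NONE
    if lfc_lof < 0 and lfc_gof > 0:
        return 1
    if lfc_lof > 0 and lfc_gof < 0:
        return 2
    if lfc_lof > 0 and lfc_gof > 0:
        return 3
    return 4


def classify_all(
    dge_lof: DGEResult,
    dge_gof: DGEResult,
    p_max: float = 0.01,
    use_padj: bool = False,
    engine: str = "internal_nb",
) -> CategoryTable:
    """Vectorized classify_gene over the intersection of tested genes.

    Both results must share the wild-type reference orientation (same
    reference label) -- otherwise logFC signs would silently flip meaning.
    """
    if dge_lof.contrast[0] != dge_gof.contrast[0]:
        raise CategoryError(
            f"contrast orientations differ: lof reference {dge_lof.contrast[0]!r} "
            f"vs gof reference {dge_gof.contrast[0]!r}"
        )
    genes = dge_lof.genes.intersection(dge_gof.genes)
    lof = dge_lof.table.loc[genes]
    gof = dge_gof.table.loc[genes]
    p_lof = (lof["padj"] if use_padj else lof["pvalue"]).to_numpy(dtype=float)
    p_gof = (gof["padj"] if use_padj else gof["pvalue"]).to_numpy(dtype=float)
    l_lof = lof["logFC"].to_numpy(dtype=float)
    l_gof = gof["logFC"].to_numpy(dtype=float)

    significant = (p_lof < p_max) & (p_gof < p_max) & (l_lof != 0) & (l_gof != 0)
    significant &= np.isfinite(l_lof) & np.isfinite(l_gof)
    cat = np.zeros(len(genes), dtype=int)
    cat[significant & (l_lof < 0) & (l_gof > 0)] = 1
    cat[significant & (l_lof > 0) & (l_gof < 0)] = 2
    cat[significant & (l_lof > 0) & (l_gof > 0)] = 3
    cat[significant & (l_lof < 0) & (l_gof < 0)] = 4
    table = pd.DataFrame(
        {
            "category": cat,
            "lfc_lof": l_lof,
            "p_lof": p_lof,
            "lfc_gof": l_gof,
            "p_gof": p_gof,
            "engines": engine,
        },
        index=genes,
    )
    return CategoryTable(
        table=table,
        contrast_lof=dge_lof.contrast,
        contrast_gof=dge_gof.contrast,
        p_max=p_max,
    )


def consensus(table_a: CategoryTable, table_b: CategoryTable) -> CategoryTable:
    """Cross-engine consensus: keep a call only when both engines agree.

    Genes called (non-none) by exactly one engine are retained with their
    category but flagged ``single_engine=True`` -- a lower-confidence tier,
    excluded from `gene_set` of the consensus unless asked for.
    """
    if table_a.contrast_lof != table_b.contrast_lof or table_a.contrast_gof != table_b.contrast_gof:
        raise CategoryError("consensus requires identical contrast designs")
    genes = table_a.table.index.union(table_b.table.index)
    cat_a = table_a.table["category"].reindex(genes, fill_value=CATEGORY_NONE)
    cat_b = table_b.table["category"].reindex(genes, fill_value=CATEGORY_NONE)
    called_a = cat_a != CATEGORY_NONE
    called_b = cat_b != CATEGORY_NONE
    agree = called_a & called_b & (cat_a == cat_b)
    single = called_a ^ called_b

    category = np.zeros(len(genes), dtype=int)
    category[agree] = cat_a[agree]
    category[single] = np.where(called_a[single], cat_a[single], cat_b[single])
    engines = np.full(len(genes), "", dtype=object)
    engines[agree] = "both"
    engines[single & called_a.to_numpy()] = table_a.table["engines"].iloc[0] if len(table_a.table) else "a"
    engines[single & called_b.to_numpy()] = table_b.table["engines"].iloc[0] if len(table_b.table) else "b"

    base = table_a.table.reindex(genes)
    fallback = table_b.table.reindex(genes)
    stats_cols = ["lfc_lof", "p_lof", "lfc_gof", "p_gof"]
    merged = base[stats_cols].where(base[stats_cols].notna(), fallback[stats_cols])
    out = merged.copy()
    out.insert(0, "category", category)
    out["engines"] = engines
    out["single_engine"] = single.to_numpy()
    # consensus category column keeps only agreed calls; single-engine tier
    # is carried in its own columns
    out.loc[single, "category_single_engine"] = out.loc[single, "category"]
    out.loc[single, "category"] = CATEGORY_NONE
    return CategoryTable(
        table=out,
        contrast_lof=table_a.contrast_lof,
        contrast_gof=table_a.contrast_gof,
        p_max=table_a.p_max,
    )


def category_overlap_tests(
    categories: CategoryTable,
    tissue_sets: list[GeneSet],
    universe: GeneSet,
    which: tuple[int, ...] = (1, 2, 3, 4),
) -> list[EnrichmentResult]:
    """Fisher enrichment of each category set against each tissue set."""
    results = []
    for cat in which:
        cat_set = categories.gene_set(cat)
        for tissue_set in tissue_sets:
            results.append(fisher_enrichment(cat_set, tissue_set, universe))
    return results
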