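"""Readers and writers for the pipeline's plain-text formats.

Everything tabular is TSV (UTF-8, tab-separated, ``#`` comment lines);
gene sets travel as GMT, ortholog maps as two-column TSV, annotations as a
minimal gene/term/description TSV, merge trees as Newick.  Readers reject
malformed input loudly, with coordinates; nothing is silently coerced.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CountMatrix, GeneSet
from .dge import DGEResult, normalize_external_table
from .enrichment import AnnotationMap, EnrichmentResult, OrthologMap


class FormatError(ValueError):
    pass


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    path: str | Path,
    sample_map_path: str | Path,
    gene_lengths_path: str | Path | None = None,
) -> CountMatrix:
    """Load a counts TSV (first column gene ids, header sample ids).

    Non-integer or negative entries, duplicate genes, and samples missing
    from the map are rejected with coordinates.
    """
    table = _read_tsv(path, index_col=0)
    if table.index.duplicated().any():
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene ids {dups[:5]}")
    for col in table.columns:
        numeric = pd.to_numeric(table[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric)) | (numeric < 0)
        if bad.any():
            gene = table.index[bad.to_numpy().nonzero()[0][0]]
            raise FormatError(
                f"{path}: invalid count at gene {gene!r}, sample {col!r} "
                f"(value {table.at[gene, col]!r}; counts must be non-negative integers)"
            )
        table[col] = numeric.astype(np.int64)
    sample_map = _read_tsv(sample_map_path, index_col=0)
    missing = [s for s in table.columns if s not in sample_map.index]
    if missing:
        raise FormatError(f"{sample_map_path}: samples absent from map: {missing}")
    lengths = None
    if gene_lengths_path is not None:
        lengths = read_gene_lengths(gene_lengths_path)
    return CountMatrix(counts=table, sample_map=sample_map, gene_lengths=lengths)


def write_count_matrix(cm: CountMatrix, path: str | Path, sample_map_path: str | Path) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="gene")
    cm.sample_map.to_csv(sample_map_path, sep="\t", index_label="sample")


def read_gene_lengths(path: str | Path) -> pd.Series:
    table = _read_tsv(path)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: gene-length table needs 2 columns (gene, length)")
    series = pd.Series(
        pd.to_numeric(table.iloc[:, 1], errors="coerce").to_numpy(),
        index=table.iloc[:, 0],
        name="length_bp",
    )
    bad = series.index[series.isna() | (series < 1)].tolist()
    if bad:
        raise FormatError(f"{path}: invalid lengths for genes {bad[:5]}")
    return series


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gene_sets_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: name<TAB>description<TAB>member1<TAB>member2..."""
    sets: list[GeneSet] = []
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name, description = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
            n_dup = len(members) - len(set(members))
            if n_dup:
                import logging

                logging.getLogger(__name__).info(
                    "%s:%d: collapsed %d duplicate members in set %r", path, lineno, n_dup, name
                )
            sets.append(GeneSet(name=name, members=members, provenance=description))
    return sets


def write_gene_sets_gmt(sets: list[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for s in sets:
            members = "\t".join(sorted(s.members))
            handle.write(f"{s.name}\t{s.provenance}\t{members}\n")


# ---------------------------------------------------------------------------
# ortholog and annotation tables
# ---------------------------------------------------------------------------

def read_ortholog_map(path: str | Path, directionality: str = "native->foreign") -> OrthologMap:
    table = _read_tsv(path, header=None, dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: ortholog map needs 2 columns (native, foreign)")
    pairs = [tuple(row) for row in table.iloc[:, :2].itertuples(index=False)]
    return OrthologMap(pairs=pairs, directionality=directionality)


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for nat, frn in omap.pairs:
            handle.write(f"{nat}\t{frn}\n")


def read_annotation_map(path: str | Path) -> AnnotationMap:
    """Minimal gene/term/description TSV (one row per gene-term pair)."""
    table = _read_tsv(path, header=None, dtype=str)
    if table.shape[1] < 2:
        raise FormatError(f"{path}: annotation table needs >= 2 columns (gene, term[, description])")
    gene_terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for row in table.itertuples(index=False):
        gene, term = row[0], row[1]
        gene_terms.setdefault(gene, set()).add(term)
        if len(row) > 2 and isinstance(row[2], str):
            descriptions[term] = row[2]
    return AnnotationMap(gene_terms=gene_terms, descriptions=descriptions)


def write_annotation_map(amap: AnnotationMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for gene in sorted(amap.gene_terms):
            for term in sorted(amap.gene_terms[gene]):
                desc = amap.descriptions.get(term, "")
                handle.write(f"{gene}\t{term}\t{desc}\n")


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def write_dge_result(result: DGEResult, path: str | Path) -> None:
    out = result.table.copy()
    out["contrast"] = f"{result.contrast[0]}->{result.contrast[1]}"
    out["method"] = result.method
    out.to_csv(path, sep="\t", index_label="gene")


def read_external_dge_table(path: str | Path, contrast: tuple[str, str], method: str = "external_table") -> DGEResult:
    """Ingest an externally produced DGE table (edgeR- or DESeq2-style names)."""
    table = _read_tsv(path)
    if "gene" not in {c.strip().lower() for c in table.columns}:
        table = table.rename(columns={table.columns[0]: "gene"})
    tab = normalize_external_table(table)
    if "padj" not in tab.columns:
        from .dge import bh_adjust

        tab["padj"] = bh_adjust(tab["pvalue"].to_numpy())
    return DGEResult(table=tab, contrast=contrast, method=method)


def write_enrichment_results(results: list[EnrichmentResult], path: str | Path) -> None:
    rows = [
        {
            "query": r.query,
            "reference": r.reference,
            "universe_size": r.universe_size,
            "query_size": r.query_size,
            "reference_size": r.reference_size,
            "overlap": r.overlap,
            "odds_ratio": r.odds_ratio,
            "pvalue": r.pvalue,
            "padj": r.padj,
            "neg_log10_p": r.neg_log10_p,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_intersections(counts: dict[tuple[str, ...], int], set_names: list[str], path: str | Path) -> None:
    """Exclusive-intersection counts with a binary signature column."""
    rows = []
    for signature, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0])):
        binary = "".join("1" if name in signature else "0" for name in set_names)
        rows.append({"signature": binary, "sets": "&".join(signature), "count": count})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
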