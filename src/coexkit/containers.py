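"""Core in-memory containers shared across the pipeline stages.

Counts live in a pandas DataFrame (genes x samples) wrapped with the sample
metadata needed downstream: which tissue and genotype each library comes
from, and per-gene transcript lengths for RPKM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SAMPLE_MAP_COLUMNS = ("tissue", "genotype", "replicate")


class CountMatrixError(ValueError):
    """Raised when a count matrix or its metadata is malformed."""


@dataclass
class CountMatrix:
    """Raw integer counts (genes x samples) plus sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id with one column per sample id.
        Entries must be non-negative integers.
    sample_map
        DataFrame indexed by sample id with columns ``tissue``,
        ``genotype`` and ``replicate``; every count column must appear.
    gene_lengths
        Optional Series of transcript lengths in bp (required for RPKM).
    """

    counts: pd.DataFrame
    sample_map: pd.DataFrame
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise CountMatrixError(f"duplicate gene ids: {dups[:5]}")
        values = self.counts.to_numpy()
        if values.size:
            if np.issubdtype(values.dtype, np.floating):
                if not np.all(np.isfinite(values)) or np.any(values != np.round(values)):
                    bad = np.argwhere((values != np.round(values)) | ~np.isfinite(values))
                    g, s = bad[0]
                    raise CountMatrixError(
                        f"non-integer count at gene {self.counts.index[g]!r}, "
                        f"sample {self.counts.columns[s]!r}"
                    )
                self.counts = self.counts.astype(np.int64)
                values = self.counts.to_numpy()
            if np.any(values < 0):
                g, s = np.argwhere(values < 0)[0]
                raise CountMatrixError(
                    f"negative count at gene {self.counts.index[g]!r}, "
                    f"sample {self.counts.columns[s]!r}"
                )
        missing = [s for s in self.counts.columns if s not in self.sample_map.index]
        if missing:
            raise CountMatrixError(f"samples missing from sample map: {missing}")
        for col in SAMPLE_MAP_COLUMNS:
            if col not in self.sample_map.columns:
                raise CountMatrixError(f"sample map lacks required column {col!r}")
        if self.gene_lengths is not None:
            lengths = self.gene_lengths.reindex(self.counts.index)
            if (lengths.dropna() < 1).any():
                raise CountMatrixError("gene lengths must be >= 1 bp")
            self.gene_lengths = lengths

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def samples_in_group(self, label: str, by: str = "tissue") -> list[str]:
        """Sample ids whose sample-map entry in column *by* equals *label*."""
        meta = self.sample_map.loc[self.samples]
        return [s for s in self.samples if meta.at[s, by] == label]

    def group_labels(self, by: str = "tissue") -> list[str]:
        meta = self.sample_map.loc[self.samples]
        seen: list[str] = []
        for lab in meta[by]:
            if lab not in seen:
                seen.append(lab)
        return seen


@dataclass
class ExpressionMatrix:
    """Normalized expression values (CPM or RPKM), genes x samples."""

    values: pd.DataFrame
    unit: str  # "CPM" | "RPKM"
    normalization: str = "none"  # "none" | "TMM"

    def __post_init__(self) -> None:
        if self.unit not in ("CPM", "RPKM"):
            raise ValueError(f"unit must be CPM or RPKM, got {self.unit!r}")
        if self.normalization not in ("none", "TMM"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids with free-text provenance."""

    name: str
    members: frozenset[str]
    provenance: str = ""

    def __init__(self, name: str, members, provenance: str = "") -> None:
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "members", frozenset(members))
        object.__setattr__(self, "provenance", provenance)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def intersection(self, other: "GeneSet") -> frozenset[str]:
        return self.members & other.members
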