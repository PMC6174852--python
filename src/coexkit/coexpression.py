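"""Tissue-mean expression profiles, Pearson co-expression, and set algebra.

The co-expression substrate is the vector of mean RPKM per tissue (one
value per tissue, replicates averaged).  A gene pair is called
co-expressed under a dual threshold: Pearson r above ``r_min`` AND the
two-sided correlation P-value below ``p_max``.  With 11 tissues the
P-value condition is the binding one (p < 0.001 requires r above ~0.855),
so both bounds are applied and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import ExpressionMatrix, GeneSet


class CoexpressionError(ValueError):
    pass


@dataclass
class TissueProfiles:
    """Mean expression per gene per tissue (genes x tissues)."""

    values: pd.DataFrame
    floor_applied: float | None = None

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise CoexpressionError("duplicate tissue labels")
        if (self.values.to_numpy() < 0).any():
            raise CoexpressionError("profiles must be non-negative")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def tissues(self) -> pd.Index:
        return self.values.columns

    @property
    def n_tissues(self) -> int:
        return self.values.shape[1]


@dataclass
class CorrelationMatrix:
    r: pd.DataFrame
    n_tissues: int
    zero_variance_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> pd.Index:
        return self.r.index


@dataclass
class CoexpressionGroup:
    """A seed gene and its significant Pearson partners."""

    seed: str
    partners: pd.DataFrame  # index gene; columns r, pvalue
    r_min: float
    p_max: float

    @property
    def mean_coefficient(self) -> float | None:
        """Average of seed-to-partner coefficients; None for an empty group."""
        if len(self.partners) == 0:
            return None
        return float(self.partners["r"].mean())

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.partners.index)

    def to_gene_set(self, include_seed: bool = True) -> GeneSet:
        members = set(self.partners.index)
        if include_seed:
            members.add(self.seed)
        return GeneSet(
            name=f"{self.seed}_partners",
            members=members,
            provenance=f"seed={self.seed} r>{self.r_min} p<{self.p_max}",
        )


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

def tissue_mean_profiles(expr: ExpressionMatrix, sample_map: pd.DataFrame) -> TissueProfiles:
    """Arithmetic mean over replicates, per tissue."""
    if expr.unit != "RPKM":
        raise CoexpressionError(f"profiles are built from RPKM, got {expr.unit}")
    tissues = sample_map.loc[expr.values.columns, "tissue"]
    empty = [t for t in tissues.unique() if (tissues == t).sum() == 0]
    if empty:
        raise CoexpressionError(f"tissue with zero samples: {empty}")
    means = expr.values.T.groupby(tissues, sort=False).mean().T
    return TissueProfiles(values=means)


def filter_expressed(profiles: TissueProfiles, min_rpkm: float = 5.0) -> TissueProfiles:
    """Keep genes whose maximum tissue-mean RPKM strictly exceeds the floor."""
    if min_rpkm < 0:
        raise CoexpressionError("min_rpkm must be >= 0")
    keep = profiles.values.max(axis=1) > min_rpkm
    return TissueProfiles(values=profiles.values.loc[keep], floor_applied=min_rpkm)


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def pearson_r(x, y) -> float:
    """Product-moment correlation of two equal-length tissue vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CoexpressionError("vectors must be 1-D and equal length")
    if x.size < 3:
        raise CoexpressionError("need >= 3 tissues for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise CoexpressionError("zero-variance vector: correlation undefined")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def correlation_pvalue(r: float, n_tissues: int, alternative: str = "two-sided") -> float:
    """P-value for a Pearson coefficient from the t transform.

    t = r*sqrt(n-2)/sqrt(1-r^2) against Student t with n-2 df.  |r| = 1
    maps to p = 0.
    """
    if n_tissues < 3:
        raise CoexpressionError("need >= 3 tissues")
    if abs(r) > 1:
        raise CoexpressionError("|r| must be <= 1")
    if abs(r) == 1.0:
        return 0.0
    df = n_tissues - 2
    t = r * np.sqrt(df) / np.sqrt(1.0 - r * r)
    if alternative == "two-sided":
        return float(2.0 * stats.t.sf(abs(t), df))
    if alternative == "greater":
        return float(stats.t.sf(t, df))
    if alternative == "less":
        return float(stats.t.cdf(t, df))
    raise CoexpressionError(f"unknown alternative {alternative!r}")


def _drop_zero_variance(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    sd = values.std(axis=1, ddof=0)
    flagged = values.index[sd == 0].tolist()
    return values.loc[sd > 0], flagged


def correlation_matrix(
    profiles: TissueProfiles, log_transform: bool = False
) -> CorrelationMatrix:
    """Symmetric Pearson matrix over all retained genes.

    Zero-variance genes are excluded and listed; optional log2(x+1)
    transform before correlating.
    """
    values = np.log2(profiles.values + 1.0) if log_transform else profiles.values
    values, flagged = _drop_zero_variance(values)
    if len(values) < 2:
        raise CoexpressionError("need >= 2 genes with nonzero variance")
    r = np.corrcoef(values.to_numpy())
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    frame = pd.DataFrame(r, index=values.index, columns=values.index)
    return CorrelationMatrix(r=frame, n_tissues=profiles.n_tissues, zero_variance_genes=flagged)


def partner_set(
    profiles: TissueProfiles,
    seed: str,
    r_min: float = 0.8,
    p_max: float = 0.001,
    log_transform: bool = False,
) -> CoexpressionGroup:
    """All retained genes with r(seed, gene) > r_min AND p < p_max.

    The dual threshold is conjunctive; with 11 tissues the p < 0.001 bound
    is stricter than r > 0.8.
    """
    if seed not in profiles.genes:
        raise CoexpressionError(f"seed {seed!r} absent from profiles (filtered or unknown)")
    values = np.log2(profiles.values + 1.0) if log_transform else profiles.values
    values, _ = _drop_zero_variance(values)
    if seed not in values.index:
        raise CoexpressionError(f"seed {seed!r} has zero variance across tissues")
    n = profiles.n_tissues
    x = values.loc[seed].to_numpy()
    mat = values.to_numpy()
    xc = x - x.mean()
    mc = mat - mat.mean(axis=1, keepdims=True)
    r = (mc @ xc) / np.sqrt((mc**2).sum(axis=1) * (xc**2).sum())
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = np.abs(r) * np.sqrt(df) / np.sqrt(np.maximum(1.0 - r * r, 0.0))
    p = np.where(np.abs(r) == 1.0, 0.0, 2.0 * stats.t.sf(t, df))
    table = pd.DataFrame({"r": r, "pvalue": p}, index=values.index).drop(index=seed)
    hits = table[(table["r"] > r_min) & (table["pvalue"] < p_max)].sort_values("r", ascending=False)
    return CoexpressionGroup(seed=seed, partners=hits, r_min=r_min, p_max=p_max)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

@dataclass
class MergeTree:
    """An agglomerative merge tree plus its leaf order."""

    linkage: np.ndarray  # scipy linkage matrix
    labels: list[str]
    leaf_order: list[str]

    def to_newick(self) -> str:
        n = len(self.labels)

        def render(node: int) -> str:
            if node < n:
                return self.labels[node]
            left, right, height, _ = self.linkage[node - n]
            return f"({render(int(left))},{render(int(right))}):{height:.6g}"

        return render(2 * n - 2) + ";"


def hierarchical_order(
    matrix: pd.DataFrame, linkage: str = "average", metric: str = "euclidean"
) -> MergeTree:
    """Agglomerative clustering of rows; returns merge tree and leaf order."""
    if len(matrix) < 2:
        raise CoexpressionError("need >= 2 items to cluster")
    dist = pdist(matrix.to_numpy(dtype=float), metric=metric)
    z = hierarchy.linkage(dist, method=linkage)
    order = hierarchy.leaves_list(z)
    labels = [str(x) for x in matrix.index]
    return MergeTree(linkage=z, labels=labels, leaf_order=[labels[i] for i in order])


def tissue_dendrogram(profiles: TissueProfiles) -> MergeTree:
    """Average-linkage Euclidean tree over tissues on log2(RPKM+1) profiles."""
    logged = np.log2(profiles.values + 1.0)
    return hierarchical_order(logged.T)


# ---------------------------------------------------------------------------
# set algebra
# ---------------------------------------------------------------------------

def exclusive_intersections(sets: list[GeneSet]) -> dict[tuple[str, ...], int]:
    """UpSet-style exclusive intersection counts.

    For each nonempty combination of set names, the number of genes that
    belong to every set in the combination and to no other set.  The counts
    partition the union.
    """
    if not sets:
        raise CoexpressionError("need >= 1 set")
    names = [s.name for s in sets]
    if len(set(names)) != len(names):
        raise CoexpressionError("set names must be unique")
    union = set().union(*(s.members for s in sets))
    counts: dict[tuple[str, ...], int] = {}
    for gene in union:
        signature = tuple(s.name for s in sets if gene in s.members)
        counts[signature] = counts.get(signature, 0) + 1
    return counts


def set_contrast(set_a: GeneSet, set_b: GeneSet) -> tuple[frozenset, frozenset, frozenset]:
    """(shared, A only, B only)."""
    shared = set_a.members & set_b.members
    return frozenset(shared), frozenset(set_a.members - shared), frozenset(set_b.members - shared)
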