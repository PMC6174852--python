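"""One-sided Fisher / hypergeometric gene-set enrichment.

The tail probability P(X >= k) for the overlap of a query set (size n) and
a reference set (size K) inside a universe of N genes is computed in log
space from log-gamma terms, so P-values far below float underflow in the
naive product form (down to ~1e-300, covering tails like 1e-82) remain
exact.  The same statistic backs term (GO / protein-family) enrichment via
a flat annotation map that can be augmented with ortholog-transferred
annotations, propagating one-to-many and many-to-one relations fully.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

from .containers import GeneSet
from .dge import bh_adjust

logger = logging.getLogger(__name__)

NEG_LOG10_CAP = 320.0  # reported for underflowed (p == 0) results


class EnrichmentError(ValueError):
    pass


@dataclass
class EnrichmentResult:
    """A 2x2 overlap test: k of n query genes hit a reference of K in N."""

    query: str
    reference: str
    universe_size: int  # N
    query_size: int  # n
    reference_size: int  # K
    overlap: int  # k
    odds_ratio: float
    pvalue: float
    padj: float | None = None

    @property
    def neg_log10_p(self) -> float:
        if self.pvalue <= 0.0:
            return NEG_LOG10_CAP
        return min(-np.log10(self.pvalue), NEG_LOG10_CAP)


def _log_hypergeom_pmf(j: np.ndarray, N: int, K: int, n: int) -> np.ndarray:
    """log C(K,j) + log C(N-K, n-j) - log C(N,n)."""
    j = np.asarray(j, dtype=float)

    def logc(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    return logc(K, j) + logc(N - K, n - j) - logc(N, n)


def hypergeometric_overlap(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail overlap probability P(X >= k), X ~ Hypergeom(N, K, n).

    Computed by log-space summation over the support, accurate deep into
    the tail (p ~ 1e-90 and below).
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N and K >= 0 and n >= 0):
        raise EnrichmentError(f"infeasible counts k={k}, K={K}, n={n}, N={N}")
    if k <= max(0, n + K - N):
        return 1.0
    support = np.arange(k, min(K, n) + 1)
    logp = logsumexp(_log_hypergeom_pmf(support, N, K, n))
    return float(min(np.exp(logp), 1.0))


def fisher_enrichment(
    query: GeneSet,
    reference: GeneSet,
    universe: GeneSet,
    alternative: str = "greater",
) -> EnrichmentResult:
    """One-sided Fisher exact test of query/reference overlap in a universe.

    Genes outside the universe are dropped from query and reference with a
    logged count (ortholog-mapped sets routinely carry unexpressed genes).
    The one-sided p equals the hypergeometric upper tail P(X >= k).
    """
    if len(universe) == 0:
        raise EnrichmentError("empty universe")
    uni = universe.members
    q = query.members & uni
    ref = reference.members & uni
    dropped = (len(query) - len(q)) + (len(reference) - len(ref))
    if dropped:
        logger.info(
            "fisher_enrichment(%s vs %s): dropped %d genes outside universe %s",
            query.name, reference.name, dropped, universe.name,
        )
    N, n, K = len(uni), len(q), len(ref)
    k = len(q & ref)
    if alternative == "greater":
        p = hypergeometric_overlap(k, K, n, N)
    elif alternative == "two-sided":
        support = np.arange(max(0, n + K - N), min(K, n) + 1)
        logpmf = _log_hypergeom_pmf(support, N, K, n)
        obs = logpmf[support == k][0]
        mask = logpmf <= obs + 1e-9
        p = float(min(np.exp(logsumexp(logpmf[mask])), 1.0))
    else:
        raise EnrichmentError(f"unknown alternative {alternative!r}")
    a, b, c, d = k, n - k, K - k, N - n - K + k
    odds = (a * d) / (b * c) if b * c > 0 else float("inf") if a * d > 0 else float("nan")
    return EnrichmentResult(
        query=query.name, reference=reference.name,
        universe_size=N, query_size=n, reference_size=K, overlap=k,
        odds_ratio=odds, pvalue=p,
    )


# ---------------------------------------------------------------------------
# annotations and orthologs
# ---------------------------------------------------------------------------

@dataclass
class OrthologMap:
    """Many-to-many ortholog pairs (native gene, foreign gene)."""

    pairs: list[tuple[str, str]]
    directionality: str = "native->foreign"

    def __post_init__(self) -> None:
        seen = set()
        unique = []
        for pair in self.pairs:
            if pair not in seen:
                seen.add(pair)
                unique.append(tuple(pair))
        self.pairs = unique

    def native_for(self, foreign: str) -> set[str]:
        return {a for a, b in self.pairs if b == foreign}

    def foreign_for(self, native: str) -> set[str]:
        return {b for a, b in self.pairs if a == native}


@dataclass
class AnnotationMap:
    """Flat gene -> set-of-terms annotation with term descriptions."""

    gene_terms: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_terms = {g: set(t) for g, t in self.gene_terms.items() if t}

    def genes_for_term(self, term: str) -> set[str]:
        return {g for g, terms in self.gene_terms.items() if term in terms}

    def terms(self) -> set[str]:
        out: set[str] = set()
        for terms in self.gene_terms.values():
            out |= terms
        return out


def build_annotation_map(
    native: AnnotationMap,
    ortholog_map: OrthologMap,
    foreign: AnnotationMap,
) -> AnnotationMap:
    """Union native terms with terms of every foreign ortholog.

    Many-to-many relations propagate fully: a native gene collects the
    terms of all its foreign orthologs, and one foreign gene annotates all
    its native orthologs.
    """
    combined: dict[str, set[str]] = {g: set(t) for g, t in native.gene_terms.items()}
    foreign_to_native: dict[str, set[str]] = {}
    for nat, frn in ortholog_map.pairs:
        foreign_to_native.setdefault(frn, set()).add(nat)
    for frn, terms in foreign.gene_terms.items():
        for nat in foreign_to_native.get(frn, ()):
            combined.setdefault(nat, set()).update(terms)
    descriptions = {**foreign.descriptions, **native.descriptions}
    return AnnotationMap(gene_terms=combined, descriptions=descriptions)


def map_gene_set(foreign_set: GeneSet, ortholog_map: OrthologMap) -> GeneSet:
    """Native genes having at least one ortholog in the foreign set."""
    members: set[str] = set()
    for nat, frn in ortholog_map.pairs:
        if frn in foreign_set.members:
            members.add(nat)
    return GeneSet(
        name=f"{foreign_set.name}_mapped",
        members=members,
        provenance=f"ortholog-mapped from {foreign_set.name} ({ortholog_map.directionality})",
    )


def term_enrichment(
    annotations: AnnotationMap,
    query: GeneSet,
    universe: GeneSet,
    correction: str = "BH",
) -> list[EnrichmentResult]:
    """Fisher enrichment of every annotated term with >= 1 query member.

    padj is Benjamini-Hochberg across all tested terms (correction="BH");
    correction="none" leaves padj None.
    """
    annotated = set(annotations.gene_terms) & universe.members
    if not annotated:
        raise EnrichmentError("no annotated genes in universe")
    q = query.members & universe.members
    term_hits: dict[str, set[str]] = {}
    for gene in q:
        for term in annotations.gene_terms.get(gene, ()):
            term_hits.setdefault(term, set()).add(gene)
    results = []
    for term in sorted(term_hits):
        ref = GeneSet(
            name=term,
            members=annotations.genes_for_term(term) & universe.members,
            provenance=annotations.descriptions.get(term, ""),
        )
        results.append(fisher_enrichment(query, ref, universe))
    if correction == "BH" and results:
        padj = bh_adjust([r.pvalue for r in results])
        for r, adj in zip(results, padj):
            r.padj = float(adj)
    elif correction not in ("BH", "none"):
        raise EnrichmentError(f"unknown correction {correction!r}")
    return results
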