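"""Fisher/hypergeometric enrichment, including an ortholog-mapped set.

Shows the one-sided (upper-tail) overlap test between gene sets in an
explicit universe, the log-space tail that stays exact deep below float
underflow in naive form, and cross-species transfer of a foreign gene set
through a many-to-many ortholog map before testing.
"""

from coexkit import GeneSet, OrthologMap, fisher_enrichment, hypergeometric_overlap, map_gene_set

universe = GeneSet("expressed", {f"g{i}" for i in range(12000)})
module = GeneSet("auxin_module", {f"g{i}" for i in range(40)})
inducible = GeneSet("auxin_inducible", {f"g{i}" for i in range(25)} | {f"g{i}" for i in range(600, 900)})

res = fisher_enrichment(module, inducible, universe)
print(f"overlap k={res.overlap} of query n={res.query_size} vs reference K={res.reference_size} "
      f"in N={res.universe_size}")
print(f"one-sided Fisher p = {res.pvalue:.3g}  (-log10 p = {res.neg_log10_p:.1f})")

# deep-tail regime: overlaps this extreme are where log-space evaluation matters
p = hypergeometric_overlap(304, 446, 1524, 16520)
print(f"\nconstructed large overlap (k=304): p = {p:.3g} -- finite and exact in log space")

# cross-species: foreign set -> native genes via many-to-many orthology
omap = OrthologMap(pairs=[("g1", "F1"), ("g2", "F1"), ("g3", "F2"), ("g900", "F3")])
foreign = GeneSet("foreign_inducible", {"F1", "F2"})
mapped = map_gene_set(foreign, omap)
print(f"\northolog-mapped set: {sorted(mapped.members)} "
      f"(F1 fans out to two native genes; F3 not in the foreign set)")
print(f"enrichment of module vs mapped set: "
      f"p = {fisher_enrichment(module, mapped, universe).pvalue:.3g}")
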