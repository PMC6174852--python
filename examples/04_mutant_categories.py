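"""Regulatory categories from paired loss/gain-of-function transcriptomes.

Simulates wild-type, loss-of-function and derepressed genotypes with
planted regulator targets, runs both mutant-vs-wild-type NB contrasts,
and classifies genes by the converse-sign rule: category 1 = activated by
the regulator (down in lof, up in derepressed), category 2 = repressed
(the converse), categories 3/4 = same-direction secondary effects.
"""

from coexkit import SimConfig, classify_all, run_dge, simulate_mutant_experiment

cfg = SimConfig(n_genes=4000, n_modules=4, module_size=25, dispersion=0.1,
                planted_log2fc=2.0, n_planted_de_per_tissue=40,
                regulator_targets=(60, 70, 150, 140), seed=2)
counts, truth = simulate_mutant_experiment(cfg)

lof = run_dge(counts, ("wild_type", "loss_of_function"), by="genotype")
gof = run_dge(counts, ("wild_type", "derepressed"), by="genotype")
cats = classify_all(lof, gof, p_max=0.01)

print("category counts (planted in parentheses):")
for c, planted in zip((1, 2, 3, 4), cfg.regulator_targets):
    print(f"  category {c}: {cats.counts()[c]:4d}  ({planted})")

for c in (1, 2):
    genes = truth.category_label[truth.category_label == c].index
    called = cats.table.loc[genes, "category"]
    print(f"planted category-{c} recovery: {(called == c).mean():.1%}")
print("categories 1/2 isolate regulator-dependent genes; 3/4 absorb the "
      "secondary feedback moving the same way in both mutants")
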