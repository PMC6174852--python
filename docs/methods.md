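# Methods

## Count model and differential expression

Counts for gene *g* in sample *i* are modeled as negative binomial with
mean μ_gi and common dispersion φ, variance μ + φμ² (the parameterization
downstream count tools share). Group means enter through offsets: with
effective library size s_i (raw column total × TMM factor), μ_gi = m_g·s_i
under the null and group-specific m under the alternative. The per-gene
test is a likelihood-ratio test: both models are fitted by a damped,
vectorized Newton solve of Σ_i (y_i − m·s_i)/(1 + φ·m·s_i) = 0 on log m,
and 2·(ll₁ − ll₀) is referred to χ² with 1 df. This is deliberately *not*
a re-implementation of any specific tool's exact test; it produces the
same three statistics (logFC, logCPM, P) with calibration that is directly
verifiable by simulation (type-I error at nominal 0.01 lands in
[0.005, 0.02] on matched-generator nulls at 3 vs 3), and externally
computed edgeR/DESeq2 tables can be ingested unchanged wherever exact
replication of those tools is wanted.

logFC is log₂ of the ratio of group-mean CPM after adding a prior count
of 0.5 scaled by relative library size — this bounds logFC for zero
counts and matches common practice. The sign convention is explicit:
positive logFC means higher in the *test* group, and every result records
its (reference, test) orientation; the paired-mutant classifier refuses
tables whose orientations disagree rather than risk silent sign flips.

### Common dispersion

φ is estimated by maximizing the Cox–Reid adjusted profile likelihood:
for each candidate φ, group means are profiled out at their MLE and the
penalty ½·log I(β̂) per gene and group (I = Σ μ/(1+φμ)) is subtracted
before summing over genes; the scalar optimization is bounded on log φ.
The adjustment matters: the *plain* profile MLE is biased low by roughly
the ratio of residual to total degrees of freedom (≈ 4/6 at 3 vs 3, i.e.
φ̂ ≈ 0.13 for a true 0.2), while the adjusted estimate recovers φ = 0.2
within [0.15, 0.25] at 2,000 genes. Estimates at the lower search bound
are clipped to 0 (Poisson). Genes with all-zero rows are excluded;
estimation requires at least one group with ≥ 2 replicates and otherwise
instructs the caller to supply φ.

### Normalization

CPM = count / column-total × 10⁶ (columns sum to 10⁶ exactly before TMM);
RPKM divides CPM by gene length in kb. TMM factors follow the
trimmed-mean-of-M-values recipe: reference column with 75th count-fraction
percentile closest to the mean; per sample, log ratios doubly trimmed
(30% on M, 5% on A by default) and combined with inverse-variance
weights; factors rescaled to geometric mean 1. Proportional libraries
yield factors of exactly 1.

## Co-expression

The substrate is the per-gene vector of tissue-mean RPKM (arithmetic mean
over replicates), floored by "maximum tissue mean strictly greater than
5 RPKM". The floor is interpreted as max-over-tissues (the weakest
reading consistent with "a minimal RPKM threshold"); an all-tissues mode
is a one-line change via `filter_expressed` on a transformed frame.
Correlation is computed on untransformed mean RPKM by default — the
co-expressed-pair definition is threshold-based, and at the thresholds in
use the choice of scale is second-order — with a log₂(x+1) option
exposed; the tissue dendrogram always uses log₂(RPKM+1) to tame the
dynamic range. Correlation significance is the two-sided t transform
(t = r√(n−2)/√(1−r²), df = n−2); |r| = 1 maps to p = 0. With the 11-tissue
design, p < 0.001 binds at r ≈ 0.847, so the dual rule "r > 0.8 AND
p < 0.001" is genuinely conjunctive and the code applies both. Partner
sets report the mean of seed→partner coefficients ("average
coefficient"); an all-pairs mean is a trivial variant the caller can
compute from the returned coefficients.

Hierarchical orderings use average linkage on Euclidean distances via
scipy's agglomerative implementation, which is deterministic for a fixed
input; merge trees are exported as Newick. Exclusive (UpSet-style)
intersection counts are computed by a direct membership scan and always
partition the union.

## Enrichment

The one-sided Fisher p equals the hypergeometric upper tail P(X ≥ k),
computed as a log-space sum of log-gamma pmf terms. This is exact (to
~10⁻¹⁴ relative against rational enumeration on all tables with N ≤ 30)
and reaches tails near the double-precision floor (~10⁻³⁰⁰) without
underflow — the regime of deeply significant overlaps in genome-scale
comparisons. Underflowed p = 0 is reported as −log₁₀p capped at 320.
The universe is an explicit, named argument recorded in every result; the
default pipeline policy is "genes passing the expression floor", the
single most result-sensitive choice this kind of analysis leaves
unstated, which is why it is a logged parameter rather than a constant.
Genes outside the universe are dropped from query and reference with a
logged count (ortholog-mapped sets routinely contain unexpressed genes).
Term enrichment treats GO / protein-family annotations as flat labels (no
ontology-graph propagation) and BH-adjusts across tested terms; the
annotation compiler unions native terms with those of all foreign
orthologs, propagating one-to-many and many-to-one relations fully.

## Regulatory categories

Categories require raw p < 0.01 in *both* mutant contrasts (adjusted-p
gating is an option), then assign by sign pattern; logFC exactly 0 in
either contrast yields no call since the pattern is undefined. Untested
genes are never imputed. The cross-engine consensus keeps a category only
when both engines agree, retains single-engine calls in a flagged tier,
and is idempotent and commutative. Sign-flipping both contrasts maps
1↔2 and 3↔4 exactly (a metamorphic identity the suite checks).

## Synthetic data

The generator emulates the target study design: 16,520 genes (default) ×
11 tissues × 3 replicates, library sizes log-normal around 10⁷ reads
(CV 0.3), NB noise at φ = 0.1 by default. Planted structure, all recorded
in a `Truth` object:

* **Modules** (default 9 × 30 genes) share a log₂ tissue archetype drawn
  once per module (SD 2.0) plus a fixed anchor bump at a distinct peak
  tissue per module — co-expression groups in multi-tissue compendia are
  largely tissue-specific, and anchoring keeps planted modules mutually
  distinguishable rather than occasionally collinear by chance.
* **Tissue-enriched genes** (default 50/tissue) get a +2 log₂ bump in one
  tissue.
* **Regulator targets** (default 112/115/501/470 for
  activated/repressed/secondary-up/secondary-down) shift by ±2 log₂ units
  in the loss-of-function and derepressed genotypes with the
  category-defining sign patterns.

Planted genes draw their baselines from the upper expression range
(log₂ offset +2, SD 1 vs SD 2 around 0 for background): study-identified
modules and targets are, by construction, detectably expressed genes.
Gene indices are allocated deterministically — modules first, then one
enriched block per tissue, then mutant target blocks — and the repressed
(category 2) block coincides with the reproductive tissue's enriched
block, so the paired designs share the planted story the pipeline is
meant to recover: a regulator, itself reproductive-tissue-enriched and
outside the planted modules, repressing the reproductive program. Two RNG
streams derive from the seed (structure vs noise), so changing replicate
counts never reshuffles planted assignments; identical seeds give
bit-identical matrices.

What the generator does **not** emulate: gene–gene correlation beyond the
planted modules, GC/length biases, batch effects, tagwise dispersion, or
compositional (mRNA-amount) shifts between tissues. Passing tests
therefore demonstrate correctness of the inference chain under a clean NB
world with planted truth — not robustness to every artifact of real
libraries; external DGE tables remain the route to exact replication on
real data.

## Numerical choices and degenerate inputs

Newton iterations on log-mean are damped (step clipped at ±5) and capped
at 25 iterations; all-zero genes are flagged with p = 1 and logFC 0.
LRT statistics are clipped at 0 before the χ² tail. Zero-variance genes
are excluded from correlation matrices and listed; a zero-variance seed
is an error naming the cause. TMM falls back to factor 1 with a warning
when trimming leaves nothing. BH is delegated to statsmodels and checked
against the step-up definition. Dispersion search spans φ ∈ [10⁻⁶, 5] on
a log grid with a boundary check to return exactly 0 for Poisson-like
data.

## Problem sizes used in validation

The validation suite exercises: all 2×2 tables with N ≤ 30 (≈46k tables)
for exact-tail agreement; 20,000 null genes at 3 vs 3 for calibration;
2,000 genes for dispersion recovery; a 2,000-gene / 5-module fixture at
φ = 0.05 for module recovery; a 5,000-gene paired-mutant fixture at
φ = 0.1 with the default target-set sizes for category recovery; and the
full default-scale (16,520-gene) pipeline twice for checksum determinism.
These sizes are the package's own choices: large enough for the binomial
noise on the measured rates to be well inside the asserted bands, small
enough to keep the whole suite in tens of seconds.

## Known limitations

Common dispersion only (no tagwise/trended shrinkage, no covariate GLMs);
correlation P-values assume the t transform's normality, optimistic for
heavy-tailed untransformed RPKM; flat term enrichment ignores the GO DAG;
the scipy linkage tie-break, while deterministic, is the library's rather
than an explicit lowest-index rule; and the generator's clean NB world
understates real-data artifacts as described above.
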