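# Methods

`isletlnc` implements the computational core of a loss-of-function study of
pancreatic islet long non-coding RNAs (lncRNAs) and transcription factors
(TFs): artificial-microRNA (amiRNA) knockdowns in a human beta-cell line
profiled on expression arrays, cross-validated against co-expression
structure in islet RNA-seq cohorts, a cis-regulation scan, and
differential expression in diabetic-donor islets. This note records the
models, the defaults, the numerical choices, and what the bundled
synthetic data can and cannot establish.

## Knockdown differential expression

Expression is analysed on the log2 scale, one gene per row. For a target,
all replicates of its amiRNAs are pooled and compared with the pooled
replicates of the five non-targeting control amiRNAs by a per-gene
two-group one-way ANOVA: the F statistic with (1, nA+nB−2) degrees of
freedom, identical to the square of the equal-variance pooled t statistic.
The effect size is `log2fc = mean(target) − mean(control)`. The gate is
`p < 1e-3` with no multiple-testing correction, matching the screen's
operating point; Benjamini-Hochberg adjustment is available separately
(`cis_disease.bh_adjust`). Degenerate genes (zero variance everywhere) get
F = 0, p = 1; zero within-group variance with distinct means gives p = 0.

## The combinatorial specificity null

RNAi can deregulate genes non-specifically. The screen's control panel of
five non-targeting amiRNA groups supports an internal null: every one of
the C(5,2) = 10 unordered 2-vs-3 splits of the control groups is treated
as a pseudo-contrast and its DE-gene count recorded; a real target's fixed
amiRNA pair is compared against every C(5,3) = 10 control triple. The two
count samples are compared by a one-sided Mann-Whitney test (alternative:
target counts stochastically larger).

The Mann-Whitney p-value is exact for combined sample sizes up to 20:
mid-ranks are assigned to the pooled counts and the number of rank
assignments at least as extreme is counted by a dynamic program over the
doubled (hence integer) mid-ranks — equivalent to enumerating all
C(n+m, m) subsets, which the test suite verifies directly. Larger samples
fall back to the tie-corrected normal approximation with continuity
correction.

**Known property: the null is mildly anti-conservative.** The ten target
comparisons reuse the same six target samples and the ten control splits
reuse the same fifteen control samples, so the twenty counts entering the
rank test are dependent. Monte-Carlo under a global null (200 screens of
10,000 genes) gives P(mw_p < 0.05) ≈ 0.10–0.14 rather than 0.05; a
counterfactual with a fresh pseudo-target for every comparison still gives
≈ 0.08, so the inflation is intrinsic to the comparison scheme, not to
this implementation. The corresponding uniformity test in the suite is
expected to fail and is kept as a record of this property. In practice
the statistic is used as a screening descriptor with observed p-values
orders of magnitude below the inflated tail (planted regulons of ~100
genes reach the one-sided minimum of ~5e-6).

## Phenotype similarity

Fold changes of genes significant at `p < 1e-3` in at least one contrast
form the genes × contrasts matrix (union semantics; provenance per gene is
retained). Contrast pairs are compared by Pearson correlation with the
two-sided t-transform p-value (df = n−2); contrasts are clustered by
average linkage on `1 − r` with columns pre-sorted by label so the result
is order-independent. "Most regulated" genes are ranked by |log2fc|, ties
broken by smaller p and then gene id; the two-knockdown scatter comparison
takes the union of each contrast's top k (default 100).

Note that positive cross-knockdown correlation requires effects in both
directions: if every planted effect had the same sign, genes exclusive to
one regulon would anti-correlate the two contrasts. The synthetic screens
therefore plant mixed-sign regulon effects, which is also what real
knockdowns produce.

## Enrichment

* **Islet-enriched genes**: focal expression strictly greater than the
  tissue-panel mean plus two sample standard deviations (computed across
  the 16-tissue panel per gene).
* **Expression-matched control sets**: genes are assigned to quantile bins
  of mean expression (default 10); each of the (default 10) control sets
  samples, without replacement and excluding the target set, exactly the
  target's per-bin counts. A deficient bin borrows from its nearest
  neighbours with a logged warning. Matching precision scales as the
  within-bin spread over √|set|; for a 694-gene set in a 10,000-gene
  universe the control-set means sit well within 0.1 log2 units of the
  target mean, while very small or extreme-tail sets match more loosely.
* **GSEA**: the classic weighted Kolmogorov-Smirnov running sum with
  weight exponent 1 — hits add `|score|^w / Σ_hits |score|^w`, misses
  subtract `1/(N − N_hits)`; the enrichment score is the signed extreme of
  the running sum, which returns to zero at the end of the ranking for any
  set with a non-empty complement (if the set covers the whole ranking
  there are no miss steps and the sum ends at +1; the score is then the
  maximal hit prefix). Significance uses gene-set permutation (random
  equal-size sets), chosen over phenotype permutation because knockdown
  designs have too few samples to permute; p gets the +1 correction and
  NES divides by the mean |ES| of same-sign permutations.
* **Hypergeometric enrichment** (module annotation): upper-tail
  `P(X ≥ k)` with scipy's hypergeometric distribution, flagged at
  `p < 1e-2`.

## Co-expression modules

The network pipeline follows the standard weighted-co-expression recipe:
Pearson correlation → soft-threshold adjacency (`|r|^β` unsigned by
default, `((1+r)/2)^β` signed available) → topological overlap matrix
`TOM_ij = (Σ_u A_iu A_uj + A_ij) / (min(k_i, k_j) + 1 − A_ij)` → average
linkage on `1 − TOM` → static tree cut → eigengenes. β is chosen as the
smallest candidate power whose signed scale-free fit R² (log-log
regression of the binned connectivity distribution) reaches 0.8, else the
best-fitting power.

The cut is static at a configurable height (default 99% of the maximum
merge height) rather than the dynamic hybrid cut of the established tool:
a static cut is a pure function of the merge heights and can be checked
against a brute-force agglomeration oracle, which the suite does. Clusters
below `min_module_size` are "unassigned"; surviving modules are renamed
M1, M2, … by decreasing size, and "major" modules are those with more
than 100 genes. The module eigengene is the first right singular vector of
the per-gene z-scored submatrix, oriented so its mean correlation with
member genes is non-negative (consequently flipping all member profiles
flips the eigengene — the orientation is deterministic, not sign-blind).

## Cis-regulation and disease cohorts

Each lncRNA is paired with the nearest coding or TF gene on its chromosome
by gene-body interval distance (0-based half-open BED coordinates, 0 when
overlapping) within 1 Mb; exact ties resolve toward the lncRNA's 5′ side,
then lexicographically. A TSS-distance mode is available behind a flag.
The pair's Pearson correlation across cohort samples, with the
t-distribution p-value (r = ±1 maps to p = 0), declares candidates at
`p < 1e-7`.

Count cohorts use a deliberately lean negative-binomial core, not a
re-implementation of a full DE package: median-of-ratios size factors
(median over genes expressed in all samples of the count over its
geometric mean); per-condition means on the normalized scale;
method-of-moments dispersion pooled across conditions and floored at
1e-8; a Wald statistic on the log2 fold change with delta-method standard
errors; BH adjustment gating at `padj < 0.05`. A condition level named
"control" is the reference. No dispersion shrinkage, no outlier refitting
— the quantities exercised downstream are the thresholding logic and
effect directions. On planted-effect simulations (|log2fc| = 2, 50 vs 15
samples) power exceeds 0.9 with the null fraction at or under the BH
budget; the mild residual FDR optimism of moment dispersions is a known
trade-off of the simplified core.

## lncRNA candidate filters

Assembled transcripts are retained when three rules all pass:
β-cell expression ≥ `min_beta_expr` (default 0.5 abundance units),
exocrine/islet ratio ≤ `max_exocrine_ratio` (default 1.0), and an H3K4me3
peak within `max_h3k4me3_distance` of the 5′ end (default 2000 bp). The
defaults are placeholders for configuration, not measured constants; the
filter reports the first failing rule per rejected candidate and is
monotone in each threshold.

## Assay normalizations

qPCR uses the 2^−ΔCt model with amplification efficiency fixed at 2,
expressed as fold over the control-amiRNA group or, for decay curves, as a
percentage of the t = 0 mean. Knockdown efficiency is
`100·(1 − fold_remaining)` with a strict >50% gate. Insulin secretion is
normalized per cell and expressed as fold over control wells at 2.8 mM
glucose; the secretion index `secreted/content` is invariant to
proportional changes of both. 3C contact signals are divided by the
intronic control-region signal of the same sample, then by the mean
interaction of the control-group samples. Protein quantification against
the mean of two reference signals is provided as `two_reference_ratio`.

## Synthetic data: what it emulates and what it does not

* **Knockdown screens** are Gaussian on the log2 scale: per-gene baseline
  N(8, 1.5²), iid replicate noise with sd 0.25 log2 units (a realistic
  technical-plus-biological spread for a clonal beta-cell line; the real
  replicate variance is not published), planted regulon shifts, and the
  target's own transcript silenced by at least 1 log2 unit (the >50%
  efficiency gate). Declared regulon overlaps copy both genes and effects
  between targets. Not emulated: probe-level structure, normalization
  artefacts, amiRNA-specific off-target signatures, batch effects.
* **Islet cohorts** follow a latent-factor model `x = λ f_module + ε`
  (population within-module correlation λ²/(λ²+σ²), 0.5 at the default
  λ = σ = 1, which the suite checks in closed form) over 64 samples, with
  biotype labels per module and cis-pairs driven by a dedicated shared
  factor of weight w (pair correlation w², default w = 0.9) placed 2 kb
  apart on a synthetic chromosome with 50 kb between loci. Not emulated:
  overlapping modules, inter-module correlation, heavy-tailed expression.
* **Count cohorts** are gamma-Poisson: lognormal gene means, gamma
  dispersions, per-sample depth factors, and log2 condition effects on the
  mean, mirroring the 50-control vs 10–15-case design. Not emulated: GC
  or length biases, outlier samples.

Consequently, passing tests demonstrate correctness of the statistical
machinery and recoverability of planted structure under these idealized
conditions; they do not certify performance on real arrays or RNA-seq,
where unmodelled structure (batch effects, off-target signatures,
correlated noise) dominates the difficulty.

## Problem sizes and seeds

The bundled analyses run at desk scale by choice: 2,000-gene screens and
cohorts, 10,000-gene null calibrations with 200 Monte-Carlo repeats,
5,000-gene count cohorts. All generators take explicit integer seeds and
are bit-reproducible; the orchestrated pipeline derives every stage seed
from the single configured seed. The end-to-end synthetic run
(`isletlnc run-all`) completes in a few seconds; the full test suite in
about a minute.

## Open design choices made here

* "ANOVA" is realized as the two-group one-way F test on gene-level rows
  (the published analysis pooled each target's replicates against all
  controls; probe-level analysis is out of scope).
* GSEA ranks by log2 fold change (the ranking key is configurable).
* The fold-change matrix uses the union of significant genes across all
  contrasts; pairwise unions are available via the per-pair API.
* "Adjacent" in the cis scan means gene-body distance within 1 Mb;
  TSS distance is a flag.
* Module detection uses the static cut described above; this is a
  documented deviation from the dynamic cut of the established tool,
  traded for oracle-checkability.
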