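# isletlnc

Analysis toolkit for pancreatic islet lncRNA / transcription-factor gene
networks: the computational pipeline behind amiRNA knockdown screens in
human beta cells and their validation in islet cohort RNA-seq.

Long non-coding RNAs are transcribed abundantly from islet-specific loci,
but establishing that they act as *bona fide* regulators requires a chain
of quantitative evidence: that silencing one changes the transcriptome
beyond what non-targeting controls do, that lncRNA and TF knockdowns move
shared gene programs, that those programs are enriched in enhancer-
associated genes beyond expression-matched expectation, that the same
genes co-vary in native islets, that some lncRNAs track an adjacent coding
gene tightly enough to suggest cis-regulation, and that candidates change
in diabetic islets. `isletlnc` implements each link of that chain as a
tested, reusable library with a CLI, plus a synthetic-data generator that
produces every input with known ground truth.

## What is implemented

| Stage | Core statistic |
|---|---|
| Knockdown DE | per-gene two-group ANOVA, F(1, n−2), gate p < 10⁻³ |
| Specificity null | all C(5,2)=10 control 2-vs-3 splits vs the target pair against all C(5,3)=10 triples; exact one-sided Mann-Whitney on DE counts |
| Phenotype similarity | Pearson r of log2 fold changes over union-significant genes; average-linkage clustering on 1 − r |
| Enrichment | weighted-KS GSEA with gene-set permutation; decile expression-matched control sets; hypergeometric module annotation (p < 10⁻²) |
| Co-expression | soft-threshold adjacency \|r\|^β → topological overlap → static tree cut → module eigengenes |
| Cis scan | nearest coding gene within 1 Mb; Pearson p < 10⁻⁷ across the cohort |
| Disease DE | median-of-ratios size factors; NB Wald test, BH padj < 0.05 |
| lncRNA filters | beta-cell expression, exocrine-ratio and H3K4me3-proximity rules |
| Assay normalization | 2^−ΔCt qPCR folds, >50% knockdown gate, GSIS secretion index, 3C contact ratios |

See `docs/methods.md` for the models, defaults and known limitations
(including the documented anti-conservativeness of the specificity null's
rank test under dependence).

## Worked example

Run the full synthetic analysis end to end:

```bash
isletlnc run-all --seed 2 --out run/
```

which prints (seed 2):

```json
{
  "seed": 2,
  "cis": {
    "n_candidates": 14,
    "n_lncRNAs_scanned": 67,
    "planted_pair_recall": 1.0
  },
  "disease_de": {
    "n_significant": 108,
    "power_on_planted": 1.0,
    "size_factor_max_rel_err": 0.01688044274679834
  }
}
```

and writes `run/report.json` with every stage's output. Reading the
report: the simulated screen plants two regulators (a lncRNA-like and a
TF-like target) whose 120-gene regulons share half their genes — their
knockdown fold changes correlate at r ≈ 0.5, the specificity null performs
its 10 + 10 comparisons and separates both targets from the control splits
at the Mann-Whitney minimum (p ≈ 5·10⁻⁶), the genes down-regulated by the
lncRNA score a strongly negative GSEA enrichment (ES ≈ −1.0, permutation
p < 0.01) while ten expression-matched control sets do not, the 64-sample
cohort yields its four planted co-expression modules with lncRNA- and
TF-enriched modules flagged, all ten planted cis-pairs are recalled at
p < 10⁻⁷, and the NB disease contrast recovers the 100 planted effects
under the BH 0.05 gate.

Individual stages are available as subcommands (`simulate`,
`knockdown-de`, `specificity`, `phenotype-corr`, `gsea`, `islet-enriched`,
`coexpress`, `cis-scan`, `disease-de`, `annotate-filter`, `assay`) and as
plain library calls, e.g.:

```python
from isletlnc import knockdown
de = knockdown.anova_de(expr, design.target_samples("LNC1"),
                        design.control_samples(), alpha=1e-3)
res = knockdown.specificity_null(expr, design, "LNC1")
print(res.control_median, res.control_iqr, res.mw_p)
```

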