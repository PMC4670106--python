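# hdbrain

Analysis toolkit for case/control bulk RNA-seq of post-mortem Huntington's
disease (HD) brain: differential expression with covariate adjustment, the
**Differential Expression Score (DES)** for gene prioritization, and a
**ranked nested-subset geneset-enrichment sweep** that dissects a long DE
gene list into functionally and transcriptionally related groups. It is
aimed at analysts working with modest post-mortem cohorts (tens of brains)
where thousands of genes pass FDR and a flat enrichment test on the full
list hides where in the ranking each biological signal lives.

## What it computes

Given a gene × sample count matrix and sample metadata (condition, age at
death, RIN, and for cases CAG repeat length, onset age, and Hadzi–Vonsattel
involvement scores):

1. **Preprocess** — drop genes with nonzero counts in fewer than half the
   samples of both groups, winsorize extreme counts at the per-gene
   per-group Tukey fence (Q3 + 3·IQR), normalize by median-of-ratios size
   factors, and variance-stabilize with
   g(x) = (2/√α)·asinh(√(αx)) for NB variance μ + αμ².
2. **Differential expression** — per-gene NB GLM
   (log E[K] = log s + β₀ + β_cond·[case] + age-bin + RIN>7 terms), Wald
   test on the condition coefficient, Benjamini–Hochberg FDR, DE call at
   padj < 0.05.
3. **DES** — DES = overall mean counts × |log2 FC| × (−log10 padj),
   re-prioritizing genes that are abundant *and* strongly changed *and*
   significant, instead of near-silent genes with extreme p-values.
4. **Enrichment sweep** — test every nested prefix (top 25, 50, 75, …) of
   the significance-ranked list against each geneset with the one-sided
   hypergeometric tail; mask p ≥ 0.05; rank sets by best sweep p; take the
   top 15 per collection; row-normalize and Ward-cluster the concatenated
   profiles into functional groups A–E. GO-style hierarchies get
   true-path annotation propagation before testing.
5. **Clinical association** — per-gene OLS of VST expression on CAG,
   CAG-adjusted residual onset, or H-V scores adjusting for RIN (cases
   only), plus an NB-GLM confounding check of the DE genes against
   cortical involvement.

A synthetic-cohort generator (NB counts, planted DE genes and genesets,
clinical covariates with CAG–onset correlation) makes every stage testable
with no external data.

## Worked example

The analysis scripts chain the full study on a synthetic cohort
(2,000 genes, 20 HD vs 49 controls, 19% DE):

```sh
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_preprocess.py
python analysis/03_differential_expression.py
python analysis/04_des_ranking.py
python analysis/05_enrichment_sweep.py
python analysis/06_clinical_association.py
```

which prints, among other lines:

```
336 of 1974 tested genes DE at FDR<0.05 (17.0%)
recovery vs ground truth: recall 0.86, empirical FDR 0.030
published DES worked examples reproduce within 5.38e-04 relative error (top row: MBP = 513824.5)
PLANTED_D25: in top-15 = True, best p at subset size 25 (best p = 3.53e-13)
PLANTED_D200: in top-15 = True, best p at subset size 200 (best p = 1.31e-28)
confound check on 336 DE genes: no gene associated with cortical involvement after FDR adjustment (min padj 0.896)
```

Read: the Wald stage recovers 86% of truly DE genes at a 3% realized FDR;
the DES arithmetic reproduces the published worked examples (the myelin
gene MBP tops the DES ranking at ~5.1×10⁵ despite a padj of only 0.003,
because of its enormous abundance); the sweep localizes both planted
genesets at exactly their planted depths; and the clinical stage
reproduces the expected negative result on a cohort where expression is
independent of the covariates.

The same stages are available as a CLI (`hdbrain simulate | preprocess |
de | score | sweep | assoc | run`) and as plain library functions
(`hdbrain.dge.nb_wald_test`, `hdbrain.enrich.enrichment_profile`, …).
`hdbrain run` executes everything end to end and writes a manifest with a
configuration hash and per-artifact checksums; identical inputs and seed
give a byte-identical manifest.

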