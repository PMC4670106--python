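# Methods

`hdbrain` implements a complete bulk RNA-seq case/control analysis for
post-mortem Huntington's disease (HD) brain cohorts: count preprocessing,
negative-binomial differential expression with covariate adjustment, the
Differential Expression Score (DES) prioritization statistic, a ranked
nested-subset geneset-enrichment sweep with integrated Ward clustering, and
per-gene clinical-covariate association. This note records the models, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Preprocessing

**Low-signal filter.** A gene is retained iff it has nonzero counts in at
least ⌈n/2⌉ samples of the HD group *or* of the control group. Retention on
either group's evidence is deliberate: the strongest disease signals in
this setting are genes expressed almost exclusively in cases (homeobox-like
genes with control means near zero), and a both-groups requirement would
discard exactly those genes. The filter is idempotent.

**Outlier trimming.** Sporadic aberrant libraries can produce single counts
orders of magnitude above a gene's typical level and dominate its fold
change. Per gene and per group, counts above the Tukey fence Q3 + k·IQR
(default k = 3, quartiles by linear interpolation) are winsorized to
⌈Q3 + k·IQR⌉. Counts stay integral, never increase, and the within-group
median is never altered (the fence is ≥ Q3 by construction). Both k and the
quantile convention are exposed; this winsorization is this package's own
documented rule, not a reproduction of any particular published trimming
procedure.

**Normalization.** Median-of-ratios size factors: reference genes are those
with a positive geometric mean across samples (nonzero everywhere); sample
j's factor is the median over reference genes of count_ij / geomean_i.
Factors are invariant to gene order and to all-zero genes; an empty
reference set is an explicit error rather than silent degradation.

**Variance stabilization.** For NB counts with variance μ + αμ², the exact
closed-form stabilizer is g(x) = (2/√α)·asinh(√(αx)); g(0) = 0, g is
monotone, and g → 2√x in the Poisson limit α → 0. A single shared α is
estimated by method of moments from within-group mean/variance pairs
(median across genes, floored at 1e−8). A shared α keeps the transform
closed-form and exactly testable; a per-gene option exists for the Wald
stage. The transformed values are treated as approximately homoscedastic
Gaussian inputs to the per-gene linear regressions.

## Differential expression

Per gene, a negative-binomial GLM with log link and offset log(size
factor):

    log E[K_ij] = log s_j + β0 + β_cond·[case_j] + Σ_b β_b·[age_j ∈ bin b]
                  + β_rin·[RIN_j > 7]

Age at death is binned 0–45 / 46–60 / 61–75 / 76+ years and RIN is
dichotomized at > 7. (The final bin is open-ended at 76: cohorts of this
kind contain many controls aged 76–89, so a bin grid with a gap there would
leave samples unmappable.) The condition coefficient divided by ln 2 is the
reported log2 fold change; Wald z = β/SE against the standard normal gives
the p-value; Benjamini–Hochberg adjustment (step-up with monotonicity
enforcement; missing p-values propagate and do not count toward m) yields
padj, and padj < 0.05 is the DE call. Ranking "by significance" breaks ties
by |LFC| descending, then gene id, for full determinism.

Deliberately **not** implemented: empirical-Bayes dispersion shrinkage, LFC
shrinkage, and independent filtering. These are package-specific behaviors
of popular DE tools; the documented MoM-dispersion Wald stage is
reproducible from this note alone, and the suite verifies it is calibrated
(type-I error ≈ 5% at 20 vs 49) and concordant with an independent NB
implementation (pydeseq2) on simulated data. Externally produced DE tables
with the same columns can be substituted downstream. Non-converged fits are
flagged, excluded from the FDR denominator, and logged.

## DES

DES = overall_mean · |log2 FC| · (−log10 max(padj, 1e−300)). The floor
prevents an infinite score when padj underflows; every realistic padj is
far above it. The score is strictly increasing in each factor, and is
computed on the FDR-adjusted p (a nominal-p variant exists behind a flag
for sensitivity analysis only). The bundled published reference tables
reproduce their printed DES column within 0.1% relative error from printed
inputs, and confirm the score's purpose: a myelin gene at ~180,000 mean
counts and modest fold change outranks a near-silent homeobox gene whose
adjusted p is 23 orders of magnitude smaller.

Descriptives over the ranked DE list: the up/down sliding-window profile
uses a 100-gene window at ranks (x, x+100], stepping by 1 (step
configurable; truncated tail windows use the genes available); biotype
composition buckets unmapped genes as "unknown" and always sums to 1;
heatmap rows are divided by their row maximum with all-zero rows passed
through.

## Nested-subset enrichment sweep

The ranked list is cut into nested prefixes of sizes 25, 50, …, plus the
full length when it is not a multiple of the step. Each prefix is tested
against each geneset with the one-sided hypergeometric tail
P(X ≥ overlap), X ~ HG(N = |universe|, K = |set ∩ universe|, n = prefix
size) — identical to one-sided Fisher's exact, so a single implementation
serves the pathway and TF collections and the GO path. The universe is the
set of genes surviving the low-signal filter (the "confidently detected"
genes), not all annotated genes, avoiding annotation-inflation bias.
Genesets are intersected with the universe at test time.

GO-style collections may carry an acyclic child→parent term hierarchy;
annotations propagate from descendants to ancestors (true-path rule)
before testing. The hierarchy-decorrelating weighting of specialized GO
tools is out of scope; with no hierarchy the GO path reduces exactly to
the plain test.

Cells with p ≥ 0.05 are masked (raw p retained). Per collection, sets are
ranked by their best (minimum) raw p anywhere in the sweep, ties by name;
the top 15 profiles per collection are concatenated, masked cells
contribute 0, each row is divided by its row sum (all-zero rows dropped
with a warning), and rows are clustered by Ward linkage on Euclidean
distance. The tree is cut into n_groups (default 5) groups labeled A, B, …
in dendrogram leaf order. The display mask uses nominal p; BH-adjusted p
per subset-size column is additionally available on the profile object.

Numerical notes. The discrete hypergeometric test is conservative: its
attained size is strictly below the nominal 5% (exactly computable;
0.02–0.04 for typical set sizes here), so the mask's false-positive rate is
validated against the exact attained size, not naive 5%. Localization of a
planted set's enrichment peak has resolution relative to its depth d:
neighboring prefixes differ by a vanishing fraction of the subset as d
grows, flattening the p-profile near its minimum, so recovery is asserted
within max(one step, 0.25·d) of the planted depth.

## Clinical covariate association

Cases only (controls carry no CAG/onset/involvement scores). Per gene,
OLS of VST expression on one covariate plus RIN; the covariate term's
two-sided t-test p is BH-adjusted across genes. The OLS is solved in
closed form for all genes simultaneously against the shared design —
numerically identical to per-gene model objects (verified against
statsmodels in the suite) and far faster. Constant covariates, n ≤ 3, and
collinear designs are explicit errors.

CAG-adjusted residual age at onset = observed onset − model-predicted
onset. Published coefficient sets are accepted as any callable
cag → predicted onset; no published coefficients are bundled. The default
is a cohort least-squares fit, log-linear (log onset ~ CAG) by default,
with a linear option whose residuals are exactly orthogonal to CAG.

The confounding check re-models raw counts of the DE genes on H-V cortical
score plus RIN with the same NB-GLM stage (size-factor offsets), adjusts
within the DE list, and flags "confounded" if any gene passes FDR < 0.05 —
the analysis that asks whether the DE signal merely reflects differential
tissue involvement.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes:
gene base means are log-normal (meanlog 4, sdlog 2: medians ~55 normalized
counts with a heavy right tail spanning ~1 to ~10^5, matching the dynamic
range such studies print); counts are gamma-Poisson NB with shared
dispersion α = 0.1 and uniform per-sample depth multipliers in [0.5, 1.5];
19% of genes are DE with |log2 FC| = 0.25 + Gamma(2, 0.5) and 54.8% of
effects up-regulated; 2% of DE genes are "case-exclusive" with control-side
mean fixed at 0.05 (not exactly 0, so NB sampling stays defined — matching
the near-zero control means such genes show in practice). Cases die younger
than controls (N(58, 10) vs N(69, 15) years), RIN is slightly lower in
cases, CAG ∈ [40, 53] with onset = 136.5 − 2.1·CAG + N(0, 5) (correlation
with CAG ≈ −0.7), and Vonsattel grades and H-V involvement scores span the
ranges seen in well-characterized HD brain banks. Default cohort size is
2,000 genes, 20 cases vs 49 controls — the real cohort's sample sizes at a
desk-scale gene count; tests and the analysis scripts state their own
sizes where they differ.

Geneset planting draws a configurable number of members uniformly from the
top d ranks of a supplied ranked list and the rest from the whole
universe, providing ground truth for sweep-recovery tests.

What the generator does *not* emulate: batch effects beyond depth, gene–
gene correlation, length/GC bias, per-gene dispersion trends, and any
relationship between expression and the clinical covariates (they are
independent by construction, which is what makes the covariate stage's
null calibration testable). Passing tests therefore demonstrate
correctness and calibration of the machinery under the assumed model, not
biological findings about real cohorts.

## Determinism and problem sizes

Every stochastic component takes an explicit seed (numpy Generator); the
pipeline manifest records the configuration hash, seed, per-stage row
counts, and SHA-256 of every artifact, and identical inputs produce a
byte-identical manifest. Simulation-based checks use 300–2,000 genes and
the 20 vs 49 sample split; the planted-recovery experiment uses 20 seeded
replicates at the default conditions. These sizes are the package's
standard desk-scale configuration and are stated in each test.

## Known limitations

* The NB-Wald stage is not bit-compatible with any released DE package;
  concordance is statistical (validated by simulation), not exact.
* A shared dispersion underfits genes with atypical mean–variance
  behavior; per-gene MoM estimates are available but noisy at small n.
* The sweep reports raw p per cell for display masking; across a sweep of
  hundreds of sets × dozens of subset sizes the masked display is
  exploratory, and the per-column BH adjustment should be consulted before
  claiming any single cell.
* True-path propagation without hierarchy decorrelation makes ancestor
  terms partially redundant with their descendants; clustering mitigates
  but does not remove this.
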