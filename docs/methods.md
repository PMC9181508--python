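# Methods

This note documents the statistical models behind each stage, the defaults
and their rationale, the synthetic-data generator's scope, and the
numerical choices that required a decision.

## Factorial design

The design is a set of inbred parental lines and F1 hybrids, each hybrid
with an explicit female and male parent.  Reciprocal hybrids (same parents,
swapped direction) are first-class: they are classified independently
against the same parent pair, and their pairwise differences are the
maternal-effect signal.  The bundled template (`study_design()`) has six
lines — two wild small-fruited (SP1, SP2), three cherry (SLC1–3), one
big-fruited (SL) — and 14 hybrids of which ten form five reciprocal pairs.

Harvest and replicate are the same block factor: each genotype is observed
once per harvest, so a genotype × harvest interaction is unestimable and no
model includes one.

## Trait statistics

**Genotype ANOVA.**  Per trait, a two-way fixed-effects model
`y = μ + genotype + harvest + ε` (type-II test of the genotype term).  The
design is balanced, so type choice is immaterial there; type II keeps
unbalanced inputs sane.

**Heritability.**  Broad-sense h² = σ²G/(σ²G+σ²e) from the variance
components of `y = μ + harvest (fixed) + genotype (random) + ε` fitted by
REML.  The model has a single variance ratio λ = σ²G/σ²e, so the fit
profiles the restricted likelihood over log λ with a bounded 1-D
optimization and direct Cholesky algebra on V = I + λZZ'.  This is exact
for the model and stable at the λ → 0 boundary, where general-purpose
mixed-model optimizers are fragile; the implementation agrees with R's
lme4 REML to at least four significant digits (cross-checked in the test
suite via Rscript).  Negative component estimates are truncated at zero.
A method-of-moments EMS estimate is the fallback for numerically
degenerate inputs and is flagged in the result.

**Correlation and clustering.**  Spearman rank correlation (average ranks
for ties, pairwise-complete over missing values, two-sided p, unadjusted
at 0.05 by default with a Benjamini–Hochberg option).  Trait clustering
standardizes each trait to zero mean / unit variance on observed values,
then average-linkage on Euclidean distances between trait profiles.
Cluster support is the plain bootstrap probability — the fraction of
sample-resampled trees in which a node's exact trait set reappears.  The
multiscale (AU) bootstrap correction used by some R packages is not
reimplemented; plain bootstrap probabilities are conservative for large
clusters, which is acceptable for a support annotation.

Scaling happens on observed values only, before distance computation;
missing entries are imputed as the trait mean (zero after scaling) for the
distance step only.

## Mode-of-inheritance classification

Gate: one-way ANOVA across P1, P2, F1 replicate values at α = 0.05
(one-way, without the harvest term, since three groups of three leave no
room for a block adjustment; the gate is deliberately simple).  Bands on
the D/A ratio as in the README table; R and D take their closed
boundaries, A is the open interior.

Numerical choices:

* **High-parent orientation.**  A = (μ_HP − μ_LP)/2 ≥ 0, so OD always
  means "beyond the high parent" and OR "beyond the low parent",
  regardless of which parent was labelled P1.  Classification is invariant
  under swapping parent labels and under common positive affine rescaling
  of all three genotypes (property-tested).
* **Degenerate additive component.**  If A < 1e-8 × pooled SD the parents
  are indistinguishable and the ratio is taken as ±∞ by the sign of D,
  classifying as OD/OR: a transgressive F1 between equal parents is the
  textbook over-dominance case.
* **Means** are arithmetic means of replicates on the analysis scale; no
  default log transform (the caller may transform first).
* **No multiple-testing correction on the gate** by default (the per-cross
  α = 0.05 convention); BH across variables within a cross is available by
  flag.
* Groups with < 2 replicates give an `insufficient data` call, distinct
  from `ns`.

**Operating characteristics.**  `mode_recovery_power` quantifies recovery
on a grid (replicates × effect size × true ratio) with Wilson intervals.
Two regimes matter.  The open-ended bands (A at d/a = 0, OR/OD at ±1.5)
are recovered reliably whenever the gate passes.  The closed bands R and D
are only 0.4 wide, so recovering d/a = ±1 at 90%+ needs the ratio
estimate's SE below ≈ 0.1 — at three replicates that means a residual SD
of about 5% of the parental gap.  At 20% of the gap, boundary-band
recovery drops to roughly chance between adjacent bands; the power table
makes this visible rather than hiding it.

## Maternal effects

Per reciprocal pair and variable, a two-sided two-sample t-test on
replicate values; pooled-variance Student's test by default (the
convention for this design), Welch by flag; unadjusted α = 0.05 with a BH
option.  Direction is reported as the female parent of the hybrid with the
larger mean, only when significant.  Joining the inheritance calls flags
variables whose mode differs between the two cross directions.

## Expression

* **Filter:** keep genes at CPM ≥ 1 in ≥ 3 samples (one full replicate
  set).  The thresholds are configuration, not inference.
* **Normalization:** trimmed-mean-of-M-values scaling factors (30% M-trim,
  5% A-trim, inverse-variance weights, reference = sample with the most
  typical upper quartile), then log2 CPM on effective library sizes with a
  library-size-proportional prior count of 0.5, making the result exactly
  invariant to a common depth multiple.
* **Differential expression:** per-gene one-factor (genotype) linear model
  on log-CPM; contrast t-tests for all C(n,2) genotype pairs using a
  moderated variance (per-gene residual variance shrunk toward the
  across-gene median with 3 prior degrees of freedom, added to the
  residual df).  BH across the full gene × contrast scan at a global
  0.05 FDR.  Reciprocal-pair contrasts are emitted separately.  This
  stage is intentionally a light-weight linear-model pipeline on
  normalized counts — the package's contribution is the downstream
  inheritance and integration analysis; a count-level negative-binomial
  GLM is an extension point, and on the simulated null the BH-controlled
  flag rate stays below the nominal FDR (tested).

## Co-expression modules and integration

Unsigned WGCNA-style network on the DE gene set: adjacency |r|^β,
topological overlap, 1−TOM dissimilarity, average linkage, static cut,
clusters under 30 genes unassigned.

* **β** is the smallest integer (≤ 20) whose connectivity distribution
  fits scale-free topology at R² ≥ 0.8 (log-log regression over ten
  equal-width connectivity bins).  Simulated block data is not scale-free
  at any power; when nothing reaches the threshold the conventional
  unsigned default β = 6 is used.
* **Static cut at dissimilarity 0.995.**  A TOM dissimilarity of 1 means
  "no shared neighborhood"; noise-gene dissimilarities pile up in a narrow
  band just below 1, while genes sharing any reproducible topological
  overlap merge well below it.  Cutting just under the asymptote therefore
  separates "some structure" from "none": tight modules survive intact,
  and pure-noise genes remain singletons that the size filter sweeps into
  the unassigned pool.  Quantile-based cuts were rejected because their
  position depends on the module/noise mix, fragmenting tight modules or
  absorbing noise wholesale at the extremes.
* **Eigengene:** first right singular vector of the standardized module
  submatrix (unit norm), sign-oriented to correlate positively with mean
  module expression so signs are reproducible.
* **Module–trait:** Pearson r with two-sided p per module × trait.
* **Enrichment:** flat hypergeometric upper tail per module × term against
  the clustered-gene universe, BH within the scan.  No ontology-graph
  propagation: term sets are taken as given.
* **Concordance:** for a (gene, trait) pair, the per-cross mode pairs from
  both call tables plus an OLS regression of trait values on the gene's
  normalized expression across samples (slope sign and R²).  Candidate
  genes are any module genes whose |r| with a module-linked trait exceeds
  0.6 (configurable); no organism-specific gene lists are built in.

## Synthetic data

The generator's job is to produce data with the structure of a real
factorial fruit-metabolite study and *known* truth, at the study's scale:
6 parents, 14 hybrids (5 reciprocal pairs), 3 replicate harvests, 68
traits, and a count matrix with module structure.

Trait model: genotypic value per line from a per-trait spec; hybrid value
= midparent + (d/a)·A + maternal shift (applied when the designated line
is the female parent); observation = genotypic value + shared per-harvest
block effect + Gaussian residual; optional exponentiation for strictly
positive, log-normal abundances.  Defaults:

* residual SD 0.5 and harvest SD 0.3 on a line-mean scale of 10 ± 2 —
  replicate CVs of a few percent, typical of ratio-normalized metabolite
  panels;
* 8 trait clusters sharing latent line values, giving within-cluster
  correlation and co-clustering;
* true potence ratios drawn per (cluster, parent pair) — reciprocal
  hybrids are genetically identical, so they share the drawn ratio and
  differ only by maternal shifts; mode probabilities (A .43, R .23,
  OR .18, OD .11, D .05) reflect the classified-case mixture reported for
  fruit secondary metabolites, and each cluster transgresses in a single
  direction or (with probability 0.35) not at all, matching the observed
  single-type consistency of transgressions;
* heterogeneous genetic signal — about one trait in eight essentially
  without genotype effect and a further sixth weak — so heritabilities
  span near-0 to 0.99 and roughly 50 of 68 traits exceed h² = 0.4, the
  distribution such panels actually show;
* 7 traits carry a ±3-residual-SD maternal shift on one reciprocal
  female, the order of maternal-effect prevalence seen for fruit
  metabolites.

Count model: negative binomial (dispersion 0.1) with log-normal library
sizes, per-gene log-means around 100, module latent factors composed of a
genotype-level score plus replicate noise, and spiked per-genotype
log-effects with declared inheritance modes for a DE subset.  The default
module-size profile (12 modules, 39–300 genes at 2,000 total) mirrors a
down-scaled DE-gene co-expression analysis.

What the generator does **not** emulate: instrument drift and batch
effects (assumed corrected upstream), missing-value mechanisms beyond
simple NA injection, count overdispersion heterogeneity across genes,
between-module factor correlation (modules are independent given
genotype), and any sequence-level structure.  Passing recovery tests on
this data therefore demonstrates the statistics are implemented and
calibrated correctly, not that the pipeline is robust to every artifact
of real instruments.

## Problem sizes

The default synthetic bundle is 60 samples × 68 traits and 2,000 genes —
large enough that all 190 genotype contrasts, the full 14 × 68 call table
and a 12-module network structure are exercised, while a complete pipeline
run stays under a minute on a single CPU.  Null-calibration tests use
400–1,000 simulated variables, chosen so binomial three-sigma bands around
the nominal rates are a couple of percentage points wide.

## Known limitations

* The DEG stage is a moderated linear model on log-CPM, not a count-level
  GLM; absolute DEG counts from the two approaches differ even when both
  control FDR.
* Static tree cut cannot split nested modules that merge below the cut
  height; dynamic tree cut would, and is the natural extension.
* Bootstrap cluster support is uncorrected (no multiscale adjustment).
* The per-cross gate ANOVA ignores the harvest block, which costs a little
  power when harvest effects are large.
* `insufficient data` handling requires ≥ 2 non-missing replicates per
  genotype per (cross, variable); no imputation is attempted.
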