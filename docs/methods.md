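# Methods

This note documents the statistical procedures implemented in
`erss_pipeline`, the choices made where the design was open, and what the
synthetic-data tests do and do not demonstrate.

## Signature score (ERSS)

**Screening.** Each candidate gene is fit in a one-covariate Cox
proportional-hazards model maximized by Newton-Raphson on the partial
likelihood with Efron's tie correction (Breslow available via
`ties="breslow"`). The screen is vectorized across genes: all fits share
the risk-set bookkeeping, so thousands of genes fit in one call. Genes
with Wald p below `alpha` (default 0.05) are retained and partitioned by
the sign of the coefficient into a risk cluster A and a protective
cluster B. Non-converged or constant genes are excluded with a warning,
never silently.

**Score.** Genes are z-scored across samples (making the score invariant
to gene-wise affine transforms and hence to assay scale). For each
non-empty cluster the first right singular vector of the samples x genes
block gives a unit-norm loading vector; per-sample scores are the
projections. Principal-component sign is intrinsically arbitrary, so each
PC1 is orientation-fixed to correlate positively with the cluster's mean
z-expression; this makes the score reproducible across linear-algebra
backends and gene orderings (property-tested). `ERSS = PC1A − PC1B`; an
empty cluster contributes zero. A single-gene cluster degenerates exactly
to that gene's z-score.

**Transfer to a validation cohort.** Two modes are exposed: `refit`
(default) re-derives the per-cluster PC1s on the new cohort using the
training clusters; `project` applies the training loading vectors to the
new cohort's own z-scores. Refit mirrors reconstruction-style validation;
project is strict signature transfer. Which was used is recorded in the
result. On cohorts drawn from one generating law the two agree at r > 0.9.

**Cutpoint.** The high/low split maximizes the absolute standardized
two-group log-rank statistic over all thresholds leaving at least
`minprop` (default 0.1, the conventional default of maximally-selected
cutpoint software) of samples on each side. The reported p-value is the
ordinary log-rank p at the chosen split and is therefore selection-biased;
it is flagged as such in every output. The search is verified against an
exhaustive-scan oracle on every instance up to n = 200.

## Survival machinery

Kaplan-Meier estimation, multivariable Cox fits (Efron ties, Breslow
baseline) and Harrell's concordance are delegated to `lifelines`; the
two-group log-rank statistic is additionally implemented in vectorized
form (it agrees with `lifelines` to 1e-15) because the cutpoint search
and null-calibration simulations evaluate it thousands of times.
Time-dependent AUC uses the cumulative-case / dynamic-control definition
with inverse-probability-of-censoring weights (via `scikit-survival`);
with no censoring it reduces exactly to pair counting (tested).
Clinical association tests: chi-square for categorical pairs, falling
back to Fisher's exact test on 2x2 tables when any expected count is at
or below 5; Wilcoxon rank-sum for a score against two levels;
Kruskal-Wallis for three or more.

A note on finite-sample calibration: at 50 subjects per group with ~80%
events, the log-rank chi-square test rejects at ~6.5% for a nominal 5%
level (identically in our implementation and `lifelines`); at 100 per
group it is within [0.035, 0.065] over 2000 null replicates. The
calibration tests therefore use 100 subjects per group.

## Immune and mutational-burden stages

**ssGSEA.** Per sample, genes are ranked by expression; a set's score is
the sum over the ranked list of the difference between the rank-weighted
(rank^exponent, normalized within the set) in-set ECDF and the unweighted
out-of-set ECDF. The default exponent is 0.25; scores depend on
expression only through within-sample ranks (tested). Optional
normalization divides the whole matrix by its global score range.

**ESTIMATE-style purity.** Stromal and immune scores are unnormalized
ssGSEA scores (exponent 0.25) of two signature sets; their sum maps to
tumor purity via the published cosine transform
`purity = cos(0.6049872018 + 0.0001467884 * score)` (so a combined score
of zero corresponds to purity ~0.8225). The curated stromal/immune
signature gene lists are not bundled; callers supply their own signature
sets, and simulation runs use synthetic signatures drawn from the
simulated gene universe (`synthdata.make_signature_collection`, clearly
documented as synthetic). Out-of-range purities are flagged, not clipped.

**TMB.** Mutations per callable megabase, with the callable size an
explicit parameter (default 38 Mb, a common whole-exome convention) and
the counted classes defaulting to the nonsynonymous MAF categories
(Silent excluded). The high/low split defaults to the cohort median. The
composite ERSS x TMB stratification drops empty strata with a warning and
reports the 4-group (or fewer) log-rank test.

## Risk model

The nomogram-equivalent model is a multivariable Cox fit (score + age +
stage by default). Predictions use
`S(t|x) = S0(t)^exp(beta . (x − xbar))` with the Breslow baseline at the
covariate means. The points scale follows the standard nomogram
convention: the covariate with the largest |beta| x range spans 100
points, all others are linear in beta.x. Harrell's C gets a percentile
bootstrap CI over subjects (default B = 200). Calibration bins subjects
into quantile groups of predicted survival, compares against the
group-wise KM estimate at the horizon, and optionally subtracts a
bootstrap-refit optimism estimate from the predictions. Decision curves
use net benefit `TP/n − FP/n . p_t/(1 − p_t)`; censoring before the
horizon is handled by Kaplan-Meier accounting of the event fraction
within the treated group (with no censoring this reduces to direct
counting, tested against the closed formula).

## Co-expression stage

An unsigned adjacency `|cor|^beta` (unsigned is the historical default;
the sign convention is not material to the planted-structure tests) is
built at the smallest soft threshold whose connectivity histogram fits a
scale-free law at signed R^2 >= target (default 0.9). The fit regresses
log10(frequency) on log10(mean connectivity) over ten equal-width
connectivity bins; when no candidate reaches the target the argmax is
used with a warning. Note that independent-noise matrices can themselves
show moderately high scale-free fit at small sample sizes, so the fit
statistic is a heuristic for choosing beta, not a test of network
realism. Topological overlap follows
`TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` and is verified
against a triple-loop reference to 1e-12. Modules come from
average-linkage clustering of `1 − TOM` with a static cut (the cut height
defaults to the largest grid height yielding at least two modules of
`min_size`, logged); modules below `min_size` (default 50) fall back to
grey, and modules whose eigengenes correlate above `1 − merge_height`
(default merge height 0.3) are merged iteratively. Module eigengenes are
orientation-fixed PC1s of the z-scored module genes. Hub genes rank by
module membership (correlation with the eigengene), ties broken by
intramodular connectivity — a deterministic, database-free stand-in for
multi-algorithm hub voting.

## Case-control arm

Odds ratios use the cross-product with Woolf (log-normal Wald) 95%
intervals; zero cells get the Haldane-Anscombe +0.5 correction and are
flagged; a fully zero margin is an error. The saturated logistic model
reproduces the 2x2 estimate and interval to numerical precision, and this
equivalence is property-tested over random tables. Hardy-Weinberg uses
the 1-df Pearson chi-square against expected proportions from the
estimated allele frequency. Logistic regression is maximum likelihood
(Newton); rank-deficient designs and perfect separation are rejected with
diagnostics rather than reported. Crossover analysis builds
joint-category indicators against the protective-genotype/unexposed
reference cell in a single fit, with optional age adjustment (age enters
as a continuous covariate). Additive interaction reports
`RERI = OR11 − OR10 − OR01 + 1`, `AP = RERI/OR11` and
`S = (OR11 − 1)/((OR10 − 1) + (OR01 − 1))` with delta-method 95%
intervals on the fitted covariance (the S interval on the log scale,
following the Hosmer-Lemeshow formulation); S is reported as undefined
when its denominator is non-positive. The identity RERI = 0 iff AP = 0
iff S = 1 holds exactly and is tested, and the delta-method RERI interval
agrees with a 10,000-draw parametric bootstrap from the same covariance
within 5% on a small-covariance fixture. Allele-model (per-allele) odds
ratios require the full CT/TT split and are only available from full
genotype input.

## Synthetic data

The generators are pure functions of their spec (including the seed) and
return truth records sufficient to verify recovery.

**Expression cohort.** Per-gene Gaussian baselines (mean ~ N(6, 1), noise
SD 1) on a log2-like scale; tumors are shifted by +-`de_effect` (default
1.0) on planted up/down blocks (defaults 150 + 150 of 2000 genes; 400
tumors, 100 normals). The prognostic clusters (defaults 12 risk and 2
protective genes, inside the DE blocks) additionally share a per-sample
latent factor (SD 1.0): prognostic signatures in practice are
co-expressed pathway modules, and without within-cluster correlation a
cluster's first principal component is a random direction rather than the
cluster's common signal, making PC1-based scoring meaningless. The latent
hazard score `s_i = beta_A . mean_expr(A) + beta_B . mean_expr(B)`
(centered; defaults +-0.8) drives exponential survival times
(proportional hazards holds exactly), and uniform censoring `U(0, c_max)`
has `c_max` solved numerically so the expected censored fraction matches
`censor_rate` (default 0.3). Normal samples carry an
administrative-censoring placeholder so one clinical table covers the
cohort; survival stages operate on the tumor group.

**Mutations.** Per-sample Poisson counts with MAF-style classes (Silent
drawn at 20%).

**Case-control.** Genotypes under Hardy-Weinberg at minor-allele
frequency `q` (default 0.05); exposure Bernoulli (default prevalence
0.3); case status from a prospective logistic model with planted log-ORs
for the dominant genotype effect (default 0.6), the exposure (default
1.8) and their product (default 1.0), intercept solved to hit the target
case fraction. Defaults mirror a hospital-based study of non-smoking
women (467 cases / 395 controls, age ~ N(56.5, 11.5)).

What passing tests show: the estimators recover what the generators
plant, at the planted effect sizes, under exact proportional hazards,
independent censoring, Gaussian noise and a single biallelic locus. They
do not show robustness to real-data features the generators omit —
platform/batch idiosyncrasies beyond location/scale, heavy-tailed or
count-scale expression, linkage disequilibrium, retrospective sampling,
or non-proportional hazards.

## Numerical choices and problem sizes

- Newton-Raphson Cox steps are clipped to +-2 per iteration; convergence
  is a step below 1e-9; non-convergence excludes the gene with a warning.
- Batch adjustment aligns each gene's per-batch mean and SD to the pooled
  values (location/scale only, no empirical-Bayes shrinkage); a
  zero-variance gene within a batch is shifted only.
- The DE significance flag uses raw p < 0.05; BH-adjusted values are
  reported alongside.
- Preranked GSEA permutes gene labels (not phenotypes); NES divides ES by
  the mean same-sign permuted |ES|; nominal p has a 1/n_perm floor; FDR q
  follows the pooled-null NES-tail ratio.
- Simulation-based tests use reduced problem sizes chosen for tight
  Monte-Carlo behavior at suite scale: 200-2000 genes, cohorts of
  150-400 tumors, 2000 null replicates for calibration checks, 50 seeds
  at 20,000 subjects for case-control CI coverage, 10-20 seeds for
  recovery rates. The full-cohort defaults run in the pipeline itself.

## Known limitations

- No proportional-hazards diagnostics, competing risks, or penalized
  signature variants.
- The maximally-selected cutpoint p-value is not corrected for selection.
- Static (not dynamic) tree cut in module detection; module counts on
  real data will differ from dynamic-cut software.
- No external databases are bundled (GO/KEGG, protein-interaction
  networks, curated immune or stromal signatures); all gene sets are
  caller-supplied GMT files.
- Drug-response prediction is out of scope (requires external training
  data).
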