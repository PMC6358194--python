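# Methods

This note documents the models, numerical choices and limitations behind
the package. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## The weighted genetic risk score

For an individual genotyped at `n` of a panel's `N` biallelic SNPs, the
score is `(N / n) · Σ Wᵢ Xᵢ` over the genotyped SNPs, with `Wᵢ = ln(ORᵢ)`
and `Xᵢ` the effect-allele count. The rescaling assumes the missing SNPs
are missing at random: the observed per-SNP burden is extrapolated to the
full panel. Two consequences drive the design:

* **Exclusion rule.** A score resting on very few SNPs makes that
  extrapolation meaningless, so samples genotyped below `min_genotyped`
  SNPs (default 2, configurable) are removed before analysis and the count
  is always logged.
* **Strict allele semantics.** A VCF record is matched to the panel by
  exact id *and* exact `{REF, ALT}` = `{effect, other}` allele set. No
  strand flipping or frequency-based disambiguation is attempted — a silent
  strand error corrupts every score, so mismatches are hard errors.
  Missing calls are `./.`/`.` in VCF and `NA` in the dosage/phenotype
  dialects; no other sentinel is accepted. Sex is coded 0 = female,
  1 = male throughout.

Scores are categorised into four groups with thresholds at mean − SD, mean
and mean + SD of a reference population; the sample SD uses the n − 1
denominator and intervals are left-closed above ([m, m+s) etc.), so a score
exactly on a threshold falls in the upper group. The reference defaults to
the *cases* of the same cohort, computed separately per cohort: the
recurrence analyses are case-only and the cohorts' score distributions
differ, so a pooled or case+control reference would shift group boundaries
between analyses. Both choices are supported through the
`reference_scores` argument.

## Synthetic cohorts

The motivating data are access-controlled, so the simulator is a
first-class module rather than a fixture. It is a logistic generative
model chosen by this package (the underlying study is observational and
prescribes none):

* Genotypes: independent SNPs in Hardy–Weinberg equilibrium,
  `Xᵢ ~ Binomial(2, pᵢ)`. No linkage disequilibrium and no population
  stratification are modelled.
* Disease: `P(case | X) = σ(a₀ + Σ Wᵢ Xᵢ)` — the panel weights are the
  generative per-allele log-odds, so the raw score is exactly the genetic
  liability. Cohorts with a fixed case/control composition are drawn by
  rejection sampling from this population model, which reproduces
  case ascertainment: cases are genuinely enriched for risk alleles, which
  is what separates case and control score means (≈ 6.4 vs ≈ 5.4 under the
  shipped defaults — the scale of the published cohorts).
* Diathesis features (cases only): each feature is
  `Bernoulli(σ(a_f + γ_f · wGRS))` with γ_f = ln 1.2 by default.
* Recurrence (cases only): `Bernoulli(σ(a_r + β · wGRS + Σ δ_f f))`, with
  per-unit β = ln 1.18 (cohort A) / ln 1.22 (cohort B) and feature effects
  δ in the 1.4–2.0 OR range, early onset the strongest — matching the
  ordering of the published univariable feature→recurrence estimates.
* Sex: Bernoulli(0.75) male, independent of genotype; 3:1 is the
  approximate male:female ratio of the study populations.

**Calibration.** The free intercepts (a₀, a_f, a_r) are solved by
one-dimensional root finding on a fixed internal calibration sample of
40 000 genotype draws so that the marginal prevalences hit their targets:
case fraction 0.5 during sampling; among cases, family history 45%, early
onset 40%, bilateral 63% (cohort A) / 40% (cohort B), ectopic 12%, and
recurrence 45%. Bilateral and ectopic targets are the study's reported
extremes (most and least common feature); family history, early onset and
recurrence prevalences are not printed in the text and are set to values
typical of surgical Dupuytren's cohorts. The calibration seed is fixed and
independent of user seeds, so configs are stable across runs.

**Shipped panel.** The published 26-variant panel lives behind controlled
access, so the default panel is synthetic: 26 SNPs with odds ratios
1.11–1.98 and effect-allele frequencies 0.16–0.63, chosen so the raw score
of a random individual has mean ≈ 5.9 and variance ≈ 1.2. With a liability
slope of 1 this puts case means near 6.3, control means near 5.4, and the
observed range roughly 3.5–9.8, i.e. the published score scale. Real
panels are supplied as a weights TSV.

**Missingness** is MCAR: every genotype cell and every imputable phenotype
cell (sex, family history, early onset, bilateral, recurrence — never
ectopic, which the study's chain had complete, and never case status) is
masked independently at its configured rate. Cohort B uses a genotype
missingness of 0.15, reflecting a cohort directly genotyped at ~22 of the
26 loci; cohort A uses 0.01. MCAR is the one mechanism under which the
parameter-recovery tests have exact targets; missingness-by-covariate
(MAR) would need the masking step extended with a covariate model, which
the `apply_missingness` seam allows but the package does not ship.

**Seeding.** One master seed spawns named substreams (genotypes,
phenotypes, missingness, one per imputation chain, one per cohort) via CRC
keyed `SeedSequence` spawn keys, so adding a stage never perturbs the
draws of another and every pipeline run is byte-reproducible.

What passing simulator-based tests shows, and what it does not: recovery
and coverage results demonstrate correctness of the estimators under the
generative model's assumptions (independent HWE SNPs, logistic links,
MCAR). Real cohorts violate these in known ways — linkage disequilibrium,
ascertainment through surgical referral, informative missingness — so the
tests validate the software, not the epidemiology.

## Imputation

Chained equations with the study's variable set (recurrence, wGRS, family
history, early onset, ectopic disease, bilateral disease, sex); ectopic is
a predictor but is only imputed when it actually has missing values.
Choices the method family leaves open:

* Conditional models: Bayesian-draw logistic regression for binary
  variables (coefficients drawn from the asymptotic normal at the MLE,
  then a Bernoulli draw) and normal linear regression with drawn residual
  variance for the continuous score. The score is imputed *on the score
  scale*, not via genotypes, matching a chain whose input variable is the
  score itself. Predictive mean matching is not currently offered.
* Visit order: ascending missingness rate, ties broken by plan order.
* Initialisation: random draws from each variable's observed values,
  independently per chain.
* Separation guard: if a conditional logistic fit separates, it is
  refitted with a ridge penalty of 1e-6 and a warning is logged; observed
  cells are never modified in any case.
* Defaults m = 75, cycles = 100; analyses in this repository run
  scaled-down values (m = 3–10, cycles = 5–20) through configuration, which
  keeps the demo and test problems at desk scale while exercising the
  identical code path.

Pooling follows Rubin's rules: pooled estimate = mean, total variance =
within-mean + (1 + 1/m) × between-variance, intervals and p-values from a
t distribution with the Barnard–Rubin degrees-of-freedom adjustment
(complete-data df taken as n − k unless supplied). Per-variable chain
means per cycle are retained for convergence diagnostics.

## Association models

Logistic and multinomial (softmax) regression are fitted by Newton–Raphson
on the exact likelihood with a step-halving guard, so the log-likelihood
never decreases. Convergence requires gradient max-norm < 1e-8 (cap 50
iterations); because the attainable gradient floor scales with n, a Newton
step at machine precision (max |Δβ| < 1e-10·(1 + max |β|)) is also accepted
as converged. The covariance is the inverse observed information;
intervals are Wald with z = 1.959964 — the convention of the standard
statistics packages whose output the published tables reflect. No
multiple-testing correction is applied (p < 0.05 convention).

Separation is an explicit error, not a silent huge odds ratio: divergent
coefficients (|β| > 15) abort the fit. Two places soften this
deliberately: imputation conditionals fall back to a ridge fit (above), and
the diathesis-count table flags a count level as unavailable when its
(count = k vs count = 0) indicator regression separates — with four binary
features, the all-four cell is legitimately tiny in small cohorts.

Table-level analyses (per-unit score→outcome, recurrence by score
category vs the lowest category, recurrence by diathesis count, and the
multinomial diathesis↔category table) accept either one completed dataset
or an imputed stack; stacks are fitted per dataset and pooled by Rubin's
rules. Diathesis↔score multinomial models are univariable per feature (a
joint model is a one-line design change through `fit_multinomial`), and
score categories are re-derived within each completed dataset from its own
case scores, since the imputed score varies across datasets.

## Meta-analysis

Fixed-effect inverse-variance pooling on the log-OR scale: weights
1/se², pooled SE (Σw)^-1/2, normal p-values. Cochran's Q and I² are
computed for information but never switch the model — the two-cohort
design fixes the fixed-effect choice. Within-cohort Rubin pooling happens
first; the meta-analysis then combines the two pooled per-cohort
estimates. Published OR (95% CI) triples can be converted back to
(log-OR, SE) via the Wald relation se = (ln hi − ln lo)/(2·1.959964), with
a warning when the interval is asymmetric on the log scale beyond 2%.

## Pipeline

`run_pipeline` executes simulate → score → impute → associate → meta from
a single config and master seed. In simulation mode the cohorts are first
*written* in the external formats and read back, so the exercised analysis
path is identical to a run on user files. Every artifact is headed
TSV/CSV plus a JSON sidecar (stage, inputs, seed, version); recorded paths
are relative to the run directory and no timestamps are written, so a
fixed (config, seed) pair reproduces the output tree byte for byte.
Problem sizes in the shipped demo (1200 + 800 and 600 + 400 samples,
m = 3, cycles = 5) and the acceptance script (full cohort sizes,
m = 10, cycles = 20) are the package's chosen desk-scale working points;
all sizes are configurable.

## Known limitations

* No imputed-genotype dosage fractions, PLINK binary formats, or BCF
  streaming; no per-SNP association testing.
* The simulator models neither linkage disequilibrium nor population
  stratification nor referral ascertainment.
* No time-to-recurrence (survival) modelling and no subgroup analyses by
  initial severity or treatment — recurrence enters strictly as a binary
  phenotype.
* MICE offers no MAR sensitivity analysis; diagnostics are limited to
  per-cycle chain means.
* Wald (not profile-likelihood) intervals throughout; with very sparse
  cells Wald intervals are known to be approximate, and the separation
  guard turns the worst cases into explicit errors instead.
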