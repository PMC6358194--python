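# wgrs — weighted genetic risk scoring for Dupuytren's disease recurrence

Dupuytren's disease is a fibroproliferative disorder of the palmar fascia
with high recurrence after surgery. Four clinical features — the
Dupuytren's *diathesis*: onset before age 50, bilateral disease, ectopic
fibrotic lesions, and positive family history — mark an aggressive course.
This package implements a case-only genetic epidemiology workflow that asks
whether an individual's polygenic burden, summarised as a **weighted genetic
risk score (wGRS)** over a panel of susceptibility SNPs, predicts surgical
recurrence over and above those clinical features, and lets the whole
analysis be rehearsed end-to-end on simulated cohorts.

It is aimed at statistical geneticists and biostatisticians who want a
tested, scriptable implementation of each stage: score computation from VCF
or dosage genotypes, multiple imputation of missing clinical data, adjusted
logistic association, and two-cohort meta-analysis.

## The score and the analysis

For an individual genotyped at *n* of the panel's *N* SNPs,

```
wGRS = (N / n) * Σᵢ Wᵢ · Xᵢ,      Wᵢ = ln(ORᵢ),  Xᵢ ∈ {0, 1, 2}
```

where the sum runs over the genotyped SNPs, `Wᵢ` is the natural log of the
per-allele odds ratio and `Xᵢ` the effect-allele count. The `N/n` factor
rescales partially genotyped individuals onto the full-panel scale.
Individuals genotyped at fewer than 2 SNPs are excluded (a one-SNP score
violates the missing-at-random logic behind the rescaling).

Downstream, the package provides:

* **Categorisation** of scores into four groups split at mean − SD, mean,
  and mean + SD of a reference population (cases, by default), with
  left-closed upper intervals.
* **Multiple imputation by chained equations** (default m = 75 datasets,
  100 cycles) over recurrence, wGRS, family history, early onset, ectopic
  disease, bilateral disease and sex, with Rubin's-rules pooling
  (Barnard–Rubin degrees of freedom) of all downstream estimates.
* **Association models**: Newton–Raphson logistic and multinomial logistic
  regression with Wald 95% CIs — per-unit wGRS→recurrence odds ratios
  (unadjusted and diathesis-adjusted), recurrence by score category,
  diathesis-feature counts, and diathesis↔score multinomial tables.
* **Fixed-effect inverse-variance meta-analysis** of per-cohort log odds
  ratios, including back-transformation of published OR (CI) triples.
* A **synthetic cohort generator** (Hardy–Weinberg genotypes, logistic
  case/diathesis/recurrence models, MCAR missingness, case quota sampling)
  that reproduces the two-cohort structure of the motivating study —
  roughly 6126 and 1730 surgical cases, 3:1 male:female, bilateral disease
  the most common feature and ectopic the rarest — so every stage is
  testable without access-controlled data.

The shipped 26-SNP panel is a synthetic placeholder on the published effect
scale; substitute the real panel by passing your own weights TSV
(`snp_id, chrom, pos, effect_allele, other_allele, or`).

## Worked example

Run the built-in scaled two-cohort demo (simulate → score → impute →
associate → meta-analyse; deterministic for a fixed seed):

```
$ wgrs run-all --demo --out demo_run --seed 7
manifest: demo_run/manifest.json
uk: per-unit recurrence OR unadjusted=1.291, adjusted=1.232
nl: per-unit recurrence OR unadjusted=1.339, adjusted=1.330
meta: per-unit recurrence OR unadjusted=1.309, adjusted=1.266
```

The `uk` cohort here is simulated with a generating per-unit odds ratio of
1.18 and the smaller `nl` cohort with 1.22; the printed unadjusted ORs are
the Rubin-pooled estimates recovered from the masked, imputed data (the
unadjusted OR sits above the generating value because the diathesis
features are themselves score-dependent and mediate extra risk), and the
`meta` line is the inverse-variance combination of the two cohorts. Each
cohort directory contains `scores.tsv` (raw sum, n genotyped, rescaled
score, category), the imputed stack, the association tables and a Q-Q
coordinate file; every artifact has a JSON sidecar recording stage, inputs
and seed.

The same stages are available as `wgrs simulate`, `wgrs score`,
`wgrs impute`, `wgrs associate` and `wgrs meta`, or as library calls
(`wgrs.compute_wgrs`, `wgrs.mice_impute`, `wgrs.fixed_effect_meta`, ...).

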