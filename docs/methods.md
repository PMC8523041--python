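# Methods

## Scope and data flow

The package implements a three-stage analysis of gene–environment
interaction for BMI on top of a standardized polygenic score (PRS):

1. **Scoring** — weighted sums of effect-allele dosages from a per-variant
   weight table; optional restriction to genome-wide significant variants
   (GRS, strict p < 5×10⁻⁸) and locus-exclusion windows (e.g. a lead SNP
   ± 100 kb, boundary inclusive) for sensitivity reruns.
2. **Association and interaction testing** — score–trait associations,
   risk-factor–BMI associations, and the PRS × risk-factor interaction scan,
   each under its own study-wise Bonferroni family; a quadratic-score
   non-linearity check; a logistic check that activity status is not itself
   driven by the score.
3. **Stratification criterion** — a percentile cut-off grid search that
   maximizes R² of a threshold-interaction model, a criterion model with
   nested comparators, and fixed-percentile validation in an independent
   cohort.

Upstream steps (genotype calling, imputation, LD-aware weight estimation,
genetic PC computation, questionnaire scoring) are out of scope: the weight
table, dosage matrix, and raw phenotype measures are inputs.

## Regression engine

All models are expressed in a small formula grammar (`1`/`0` intercept
control, `C(x)` treatment-coded categoricals, `I(x > v)` indicators, `a:b`
products) and fitted with statsmodels behind a uniform surface:

* **OLS** for explained variance (R²), residualization, and the cut-off
  search (the search solves each of the 100 no-intercept designs by least
  squares directly; a brute-force per-percentile reimplementation in the
  test suite agrees to 10⁻¹⁰).
* **Robust linear fits** (IRLS, Huber psi with tuning constant 1.345, MAD
  scale re-estimated per iteration, convergence on coefficients at 10⁻⁸,
  max 50 iterations) for association and interaction p-values.  Which
  estimator produced the original study's printed estimates is not fully
  determinate; both are supported everywhere via an `estimator` argument,
  with robust as the default for inference and OLS for all R² quantities.
  Robust fits report a weighted R² flagged as diagnostic only.
* **Logistic fits** (Newton, tolerance 10⁻⁸) with Wald p-values;
  (quasi-)separation raises instead of returning unstable estimates.

Missing data are handled by listwise deletion per analysis with `n_used`
reported.  Rank deficiency raises an error naming the aliased columns
(pivoted QR).  Without an intercept, the first categorical main effect and
categoricals inside products use full (cell-mean) coding, so the search
model spans one column per activity × group cell; with an intercept,
treatment coding against a declared reference level is used throughout
(references: active, never smoker, no-or-moderate alcohol, healthy diet,
high mental health, good sleep, working with ≥ 4 years of education).

## Scoring conventions

* Dosages are declared pre-oriented to the effect allele; no allele
  flipping or strand reconciliation is attempted, and variants missing from
  the dosage matrix raise rather than being silently dropped.
* Standardization uses the scoring cohort's own mean and **population (n)
  SD**.  (A z-score of (1,2,3) is therefore ±√(3/2), not ±1.)
* Percentile ranks are nearest-rank on the empirical CDF — rank 0 for the
  minimum, ties share the lower rank; deciles are assigned by stable
  empirical rank so decile sizes differ by at most one.
* A constant raw-score vector cannot be standardized: `compute_score`
  returns the raw column with NaN standardized/ranked fields, while
  `standardize_and_rank` itself raises, since its callers require z-units.

## Cut-off criterion: numerical choices

* The indicator is strict `>` on `numpy.percentile` (linear interpolation)
  of the observed scores, both in the generator and in the search, and the
  final group labels use the same boundary: "high risk" means score
  strictly above the selected percentile value.  (The single sample at an
  exact boundary is a documented convention; percentile grids on real data
  make exact ties measure-zero.)
* Candidate percentiles whose design has an empty activity × group cell are
  skipped with a logged reason (this covers i = 0, where the below-group
  contains only the minimum sample, and high percentiles with no inactive
  carriers); rank-deficient designs are likewise skipped.  Ties in R²
  resolve to the smallest percentile.
* R² of the no-intercept search model is uncentered (1 − SSE/Σy²); since
  the response is already residualized with an intercept, centered and
  uncentered versions differ negligibly and only the arg-max matters.
* ΔR² comparisons (threshold vs linear interaction) use OLS fits of nested
  models on identical samples, so the threshold increment is non-negative
  by construction.
* Because the cut-off is optimized post hoc, its in-sample R² gain is
  upward-biased under the null — the reason validation refits the criterion
  at the fixed percentile in an independent cohort.  The percentile (not
  the score value) transports, as scores are standardized per cohort.
* Replication activity labels "sedentary"/"moderate"/"high" map to
  inactive/active/active before fitting.

## Synthetic-cohort generator

The generator emulates a middle-aged population cohort:

BMI = intercept + β_age·age + β_sex·1[male] + β_PRS·PRS
    + β_act·1[inactive] + β_lin·PRS·1[inactive]
    + β_thr·1[inactive]·1[PRS > q(p_thr)] + risk-factor offsets + ε,
ε ~ N(0, σ²).

Sign convention: active individuals have lower BMI, so positive
activity/interaction coefficients attach to the inactive group and reported
gap magnitudes map directly onto generator parameters.  A single master
seed spawns fixed substreams (weight table, genotypes, phenotypes, noise),
making every output bit-for-bit reproducible and components independently
regenerable.

Default calibration (the defaults are the package's study conditions):

* β_PRS = 1.56 kg/m² per SD and σ = 3.9 kg/m², chosen jointly so the PRS
  explains ≈ 13% of BMI variance at a realistic adult BMI SD ≈ 4.3 kg/m²;
* discovery preset: n = 5,179, age ~ U(30, 60) with β_age = 0.04 and
  β_sex = 1.0, so age and sex together explain ≈ 3% of variance;
* replication preset: n = 3,415, age ~ U(20, 60) with a larger β_age
  (0.17), three-level activity labels, and self-report bias — height
  over-reported (+1.5 ± 1.5 cm), weight under-reported (−1.5 ± 2.0 kg),
  with the analysis BMI recomputed from the biased values.  This mirrors a
  questionnaire cohort in which age/sex carry much more of the reported-BMI
  variance;
* inactivity prevalence 0.33; six further risk factors generated on their
  raw scales (smoking categories, alcohol units/week with sex-specific
  high-consumption limits at 6/12 units, diet-quality score with healthy at
  ≥ 9 points, mental-health score split at the within-sex 75th percentile,
  insomnia yes/no, employment × education composite) with BMI offsets on
  the order of the reported per-category associations;
* 20 auxiliary BMI-correlated traits (slope 0.5, unit noise) and 3
  standard-normal genetic-PC columns.

The cohort BMI means and age structure of the original populations are not
published; the intercept (24 kg/m²) and age ranges are explicit
placeholders chosen to give realistic marginals, and are configurable.

What the generator does **not** emulate: linkage disequilibrium between
variants (downstream analysis never uses LD), population stratification
(gPCs are independent noise), missing-data patterns, measurement error in
covariates, any BMI → activity reverse causation, and correlations among
risk factors.  Passing recovery tests therefore demonstrates correctness of
the estimators under the stated generative model, not robustness to these
real-data complications.

## Recovery experiments and problem sizes

The empirical checks are parameter-recovery experiments: 100 seeded cohorts
per experiment with generative parameters equal to the study's reported
estimates (activity main effect / linear interaction 0.81 / 0.33 kg/m² at
n = 4,859; 0.97 / 0.45 at n = 3,415; group gaps 0.65 / 2.07 and 0.84 / 1.66
at the 78th percentile), asserting recovery within 3× the empirical
standard error of the mean.  Type-I calibration of the interaction and
non-linearity tests uses 500 null replicates at n = 2,000, a size at which
each robust fit is fast while large-sample p-values are already accurate.

A known behavior worth stating: at this signal scale the arg-max of the
100-point R² profile is mode-centered on the generating percentile but
heavy-tailed — across 100 seeds the selection falls within ±3 percentiles
of the truth about 83% of the time (±5: ≈ 89%), with occasional selections
20 percentiles away.  The modal selection is stable.  This is the
overfitting/variance price of data-driven cut-off selection and is the
design rationale for mandatory independent replication at the fixed
percentile.

## Known limitations

* The criterion's in-sample ΔR² is not corrected for post hoc selection;
  only replication guards against it.
* Robust-fit p-values are large-sample (normal theory); at very small n the
  type-I rate can drift.
* The formula grammar supports exactly the constructs the analysis needs
  (two-way products, one categorical per product); it is not a general
  formula engine.
* The weight table's single weight column is used for PRS and GRS alike;
  score-specific weight sets require separate tables.
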