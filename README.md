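# prsgxe

Gene–environment interaction analysis of BMI with polygenic risk scores:
score construction from effect-allele dosages, PRS × risk-factor interaction
testing, a quadratic non-linearity check, and a data-driven percentile
cut-off criterion that stratifies a population into two genetic-risk groups
and is validated in an independent cohort.

## Who this is for

Epidemiologists and statistical geneticists who want to (i) compute weighted
polygenic scores (full PRS, or a GRS restricted to genome-wide significant
variants, p < 5×10⁻⁸), (ii) test whether behavioral risk factors such as
physical inactivity modify the genetic effect on BMI, and (iii) translate a
significant interaction into a simple two-group clinical criterion.  Because
cohort data of this kind are rarely public, the package ships a seeded
synthetic-cohort generator with the same statistical structure, so every
stage is testable end to end.

## The model

For a standardized score PRS (mean 0, SD 1 within the cohort) the
interaction scan fits, per risk factor,

```
BMI ~ 1 + PRS + age + C(sex) + C(risk factor) + PRS:C(risk factor)
```

with robust (Huber, t = 1.345) linear regression and a study-wise Bonferroni
threshold over the category contrasts (0.05/12 ≈ 4.17×10⁻³ for the
seven-factor set; 0.05/20 = 2.5×10⁻³ for the twenty-trait scan).

The stratification criterion is selected by a grid search: with BMI
residualized on `1 + age + C(sex)` (OLS), one hundred no-intercept models

```
BMI residuals ~ 0 + PRS + C(activity) + C(activity):I(PRS > q_i),  i = 0..99
```

are fitted, where `q_i` is the i-th empirical percentile of the observed
scores and the indicator is strict `>`.  The percentile with the highest R²
defines the low/high genetic-risk split; the final criterion model

```
BMI ~ 1 + age + C(sex) + PRS + C(activity) + C(activity):I(PRS > q)
```

is compared with its no-interaction and linear-interaction nested
counterparts (ΔR²), and refitted at the *fixed* percentile in an independent
replication cohort (the percentile, not the score value, transports, since
scores are standardized per cohort).

## Worked example

```python
from prsgxe import (discovery_config, simulate_cohort, search_cutoff,
                    fit_criterion_model, compare_models)
from prsgxe.association import categorize_risk_factors
from prsgxe.interaction import test_interaction

# synthetic discovery cohort: activity gap 0.65 kg/m^2 below the 78th score
# percentile, 2.07 kg/m^2 above it (threshold interaction 1.42)
cfg = discovery_config(seed=11, beta_activity=0.65,
                       beta_threshold_int=1.42, threshold_percentile=78)
cohort = categorize_risk_factors(simulate_cohort(cfg))

res = test_interaction(cohort, "physical_activity")
print(res.interactions.loc["inactive"])      # estimate 0.63, p = 1.6e-07

search = search_cutoff(cohort)
print(search.selected_percentile)            # 76 (score value 0.702)

ev = fit_criterion_model(cohort, search.selected_percentile)
print(ev.low_group_gap, ev.high_group_gap)   # 0.48, 2.22 kg/m^2
print(compare_models(ev))
# {'delta_r2_threshold_pct': 0.66, 'delta_r2_linear_pct': 0.44,
#  'preferred': 'threshold'}
```

Reading: in this realization the inactive–active BMI gap is 0.48 kg/m² in
the low-risk group and 2.22 kg/m² in the high-risk group (interaction
p = 3.0×10⁻¹⁰); the grid search lands two percentiles below the generating
threshold, and the threshold-interaction model adds more explained variance
(+0.66 percentage points) than the linear interaction (+0.44).

The same workflow is available from the shell:

```
prs-gxe simulate --config sim.yaml --out data/ --seed 17
prs-gxe score --weights data/weights.tsv --dosages data/dosages.tsv --out scores.tsv
prs-gxe interact --cohort data/phenotypes.tsv --scores scores.tsv --factors all --out interactions.tsv
prs-gxe criterion search --cohort data/phenotypes.tsv --scores scores.tsv --out search.json
prs-gxe run --config pipeline.yaml
```

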