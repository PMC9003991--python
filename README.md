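# vli — a vascular leak index pipeline for septic ICU cohorts

Sepsis is characterized by increased capillary permeability: infused fluid
and plasma protein escape the vasculature, so intravenous fluids — the
first-line treatment for septic hypotension — can accumulate in tissues
rather than restore perfusion. Hemoglobin cannot cross the capillary wall,
which makes the hematocrit a natural tracer: if infused fluid stays
intravascular, plasma volume expands and the hematocrit falls
(hemodilution); if fluid leaks out, the hematocrit falls more slowly or
even rises. This package implements a bedside-computable **vascular leak
index** built on that reasoning,

```
VLI = ((Hct_final − Hct_initial) / net fluid balance) × BSA × 1000
```

with hematocrit in percent points, net balance (fluid in − urine out) in
ml over the first 36 h of ICU care, and body surface area (Du Bois) in m²
as a blood-volume surrogate. The scale factor 1000 puts typical values in
single digits. Most patients have a negative index (they hemodilute);
values near zero or positive flag high leak. The package is aimed at
clinical data scientists working with ICU event streams (eICU/MIMIC-style
extracts exported to flat CSV).

What the pipeline does:

1. **io_model** — read/validate the three-table CSV interchange format
   (patients, hematocrit measurements, fluid events; times in hours from
   ICU admission, negative = pre-ICU).
2. **features** — time-windowed derivations: initial Hct (first value in
   [−12, 18] h), final Hct (mean over (18, 36] h), net balance over
   [−6, 36] h, outcome balance over (36, 84] h, BSA.
3. **cohort** — the sepsis inclusion plus a fixed-order exclusion cascade
   (bleeding/transfusion, excess other output, renal replacement therapy,
   implausible demographics, unreliable fluid charting, missing index
   ingredients, non-positive balance) with a first-match attrition table.
4. **vli_core** — the index, median imputation of its extreme 5% tails
   (fluid charting is error-prone), and quartile assignment.
5. **models** — adjusted association models: additive fits with a
   penalized cubic B-spline for the index (logit link for in-hospital
   death, identity for 36–84 h balance; severity, comorbidity when
   available, age and sex as covariates), analysis-of-deviance p-value
   for the smooth, and quartile GLMs giving Q2–Q4 vs Q1 odds ratios /
   mean differences with Wald 95% CIs.
6. **synthetic_data** — a seeded hemodilution simulator with a known
   per-patient leak fraction λ (the fraction of each infusion that leaves
   the vasculature immediately), so every stage is testable without
   credentialed database access.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data (5000 ICU stays, seed 1), writing under `results/`:

```bash
python analysis/01_simulate.py
python analysis/02_build_cohorts.py
python analysis/03_fit_associations.py
python analysis/04_report.py
```

`02_build_cohorts.py` prints the attrition of the exclusion cascade and
the index distribution:

```
Death cohort: start n=4675
  - bleeding_or_blood_products   removed    343  remaining   4332
  - excess_other_output          removed     96  remaining   4236
  - rrt                          removed    221  remaining   4015
  - erroneous_demographics       removed      0  remaining   4015
  - unreliable_fluid_data        removed    190  remaining   3825
  - missing_vli_data             removed    158  remaining   3667
  - non_positive_balance         removed      0  remaining   3667
  final n=3667
VLI median [IQR]: -2.91 [-4.47, -1.65]
mortality in death cohort: 16.0%
```

The index distribution is left-skewed with a small positive tail —
patients whose hematocrit rose despite fluids. `03_fit_associations.py`
then reports a monotone dose–response of death risk in the index:

```
death smooth: ANOVA p = 4.77e-12, EDF 1.0
Odds of in-hospital death vs Q1:
  Q2 1.62 [1.22, 2.15]   Q3 2.55 [1.90, 3.42]   Q4 2.88 [2.18, 3.81]
36-84 h fluid-balance difference vs Q1 (ml):
  Q2 180 [20, 340]       Q3 439 [262, 617]      Q4 635 [468, 803]
```

Patients in the top index quartile have ~2.9-fold the adjusted odds of
dying and accumulate ~640 ml more fluid over 36–84 h than the bottom
quartile; both smooth terms are decisive because the synthetic cohort was
generated with a positive leak effect on both outcomes. The same pipeline
is exposed as a CLI (`vli simulate / analyze / report`) for running
against real extracts in the documented CSV dialect.

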