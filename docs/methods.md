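# Methods

## The index

The vascular leak index scores how little an ICU patient hemodilutes per
unit of retained fluid:

    VLI = ((Hct_final − Hct_initial) / NB) · BSA · 1000

* `Hct_initial` — the first hematocrit in the closed window [−12, 18] h
  around ICU admission (pre-ICU emergency-department draws count; ties at
  the same earliest timestamp are averaged).
* `Hct_final` — the mean of all hematocrits in (18, 36] h.
* `NB` — net fluid balance in ml over [−6, 36] h: total intake minus
  urine output. Other outputs (drains, stool) are not part of the
  balance; they only feed an exclusion flag.
* `BSA` — Du Bois body surface area, `0.007184·kg^0.425·cm^0.725` m²,
  as a crude blood-volume normalizer. A Mosteller alternative
  (`sqrt(cm·kg/3600)`) is selectable in the run config; both are standard
  anthropometric estimators and the choice shifts the index by a few
  percent at most.

Window boundary semantics are a documented convention, since only the
endpoints are physiologic: the initial window is closed on both ends;
every later window is left-open/right-closed. Consequently a measurement
at exactly 18 h belongs to the initial window and an infusion at exactly
36 h to the first balance window — each event is counted exactly once.
All event times are hours from ICU admission; shifting all times and all
windows together leaves every feature unchanged (a tested invariance).

The index is only defined for strictly positive net balance: patients who
diurese more than they receive are not accumulating fluid, and the
clinical question the index addresses (should this patient get more
fluid?) does not arise. Zero balance is excluded along with negative.

Because charted fluid totals are error-prone, the extreme tails of the
cohort's index distribution are median-imputed before modeling: values
strictly below the 5th or strictly above the 95th empirical percentile
(linear-interpolation quantiles, the numpy default — fixed because the
imputation boundaries and the quartile cuts depend on the estimator) are
replaced by the cohort median. Boundary-equal values are retained.
Imputation never changes the median, and quartiles are always formed
after it. Quartile intervals are right-closed; a value equal to a cut
point takes the lower label, so labels are deterministic and monotone
under ties. Imputation is applied within each analysis cohort (the death
cohort and the 36–84 h balance cohort separately); a config switch reuses
the death-cohort imputation for the balance subset instead. Vectors
shorter than 20 are returned unimputed with a warning, since a 5% tail is
then empty on at least one side.

## Cohorts

Inclusion is sepsis. Exclusions run in a fixed order with first-match
attribution — each removed patient appears in exactly one attrition row,
so counts are additive: (1) bleeding diagnosis or blood products (either
invalidates the hematocrit as a dilution tracer), (2) excess other fluid
output, (3) renal replacement therapy, (4) implausible demographics
(age < 16, height outside (100, 250) cm, weight outside (20, 350) kg —
the plausibility bounds are ours, chosen to catch unit errors), (5)
unreliable fluid charting (an input flag), (6) missing any index
ingredient, (7) non-positive balance. The 36–84 h balance cohort further
removes patients who died strictly before 84 h (death at exactly 84 h is
retained; the boundary semantics are underdetermined and we fix the
strict reading) and patients with no intake or urine event in (36, 84]
(missing outcome, not zero). Patients with a missing required covariate
are dropped at model time and logged. Rerunning the cascade on its own
output removes nobody (idempotence, tested).

## Association models

Two views of each outcome, adjusted for severity of illness, chronic
comorbidity (dropped when the source records none), age and sex:

* **Additive fits.** Outcome ~ s(VLI) + covariates, logit link for death,
  identity for 36–84 h balance. The smooth is a penalized cubic B-spline,
  basis dimension 10; the penalty weight is selected by minimizing GCV
  over the grid 10⁰…10⁶ (statsmodels' PIRLS backend). Partial-effect
  curves evaluate the fit over the observed index range with covariates
  at reference (numeric means, modal sex); pointwise 95% CIs are Wald on
  the link scale, mapped through the inverse link so death-probability
  bands stay inside [0, 1].
* **Smooth-term significance** is an analysis-of-deviance: a
  likelihood-ratio chi-square between the nested *unpenalized* additive
  GLMs with and without the spline columns. We use the LRT rather than a
  Wald test on the penalized coefficients because its null distribution
  is standard, and simulation confirms calibration (rejection ≈ 5% at
  nominal 5% over 200 null replicates). If the full-size basis
  quasi-separates a binary outcome (a knot span holding only a handful of
  events), the test basis is shrunk stepwise (10 → 8 → 6 → 5 → 4 columns)
  until the likelihood is finite — the usual remedy when the basis is
  larger than the data supports; the curve keeps the full basis. In the
  degenerate noise-free Gaussian limit the PIRLS penalty machinery is
  infeasible and the unpenalized spline GLM (exact there) supplies the
  curve.
* **Quartile contrasts.** The same covariates with the index replaced by
  its quartile, Q1 (lowest) as reference: exponentiated Wald CIs give
  odds ratios for death; identity-link coefficients give mean balance
  differences in ml. With a factor-only design the logistic MLE
  reproduces the closed-form contingency-table odds ratio exactly (a
  tested oracle). A quartile with zero or all events is a hard error —
  Wald intervals are meaningless there and exact small-sample methods are
  out of scope.

No multiple-testing correction is applied across outcomes or datasets;
each dataset is analyzed and reported separately.

## The synthetic cohort generator

The generator exists so that every stage — windowing, cascade, index,
models — can be verified against a known truth. Each patient carries a
latent leak fraction λ ∈ [0, 1]: the fraction of every infusion that
leaves the vasculature immediately. This instantaneous-leak model is
deliberately the simplest mechanism the index can see; a kinetic efflux
model would not be identifiable from two hematocrit readings.

Per patient: baseline blood volume BV₀ from the Nadler sex-specific
formulas (male `0.3669·h³ + 0.03219·w + 0.6041` L, female
`0.3561·h³ + 0.03308·w + 0.1833` L, height in meters) — intentionally a
*different* anthropometric model than the BSA used by the index, so the
simulator and the estimator share no formula; red-cell volume
RCV = BV₀·Hct₀/100 is conserved exactly; each fluid event updates
intravascular volume by ΔV = (1−λ)·intake − urine and
hct(t) = 100·RCV/V(t). Measurements at a 6-hourly schedule (12-hourly
after 36 h, optional pre-ICU draw) add Gaussian noise (SD 0.9 percent
points, an analyzer-plus-short-term-variation scale) and 3% of scheduled
draws go uncharted. A urine event that would drain the plasma below the
red-cell volume is resampled to half the available plasma (logged).

Key calibrated defaults (one ICU-stay population, lognormal fluid
practice): λ ~ Beta(1.8, 1.05); total first-window intake
lognormal(log 4000, 0.45) ml arriving as ~13 front-loaded events in
(0.5, 18) h — resuscitation begins after the admission hematocrit draw;
expected urine 0.45 of retained intake. Death is Bernoulli on a logit
linear in λ (+1.5), severity (+0.018/point) and age (+0.012/year) with
intercept −4.8; the 36–84 h balance is realized exactly as
1200·λ + N(0, 1800²) ml through generated intake/urine events. Charting
stops at death or discharge. Per-patient RNG substreams are derived from
the top-level seed, so patient *i* is invariant to cohort size and
identical seeds give byte-identical files.

Under these defaults a 5000-stay cohort reproduces the intended
population shape: index median ≈ −2.9 with IQR ≈ [−4.5, −1.6] and a long
left tail, initial/final hematocrit means ≈ 36.5/30.8%, first-36 h
balance ≈ 3650 ml, hospital mortality ≈ 16%, and Spearman rank
correlation ≈ 0.91 between the per-patient index and true λ (≈ 0.79
after tail imputation, which by design discards rank information in the
extreme 10%).

What the generator does **not** emulate — and therefore what passing
tests do not establish about real data: pre-ICU resuscitation before the
first hematocrit (which attenuates the measured Hct change and degrades
the index substantially in our own ablations), hemorrhage and
transfusion, renal-replacement fluid shifts, charting unit errors, and
informative measurement timing. Excluded-flag patients (bleeding, RRT,
transfused) are simulated with ordinary physiology; their flags only
exercise the cascade.

## Problem sizes and numerics

The shipped analyses and checks use 5000-stay cohorts for single-run
estimates, 200 replicates of 1000 stays for null calibration of the
smooth test, 100 replicates of 1200 designed cohort rows for CI coverage,
and one 20 000-stay run for the dose–response ordering — sizes chosen so
each estimate's Monte-Carlo error is small relative to the effect being
checked. Acceptance-style arithmetic checks compare against independently
coded expressions at 1e−12 relative tolerance; quantiles everywhere use
the linear-interpolation estimator; all randomness flows from explicit
integer seeds.

## Known limitations

* The index conflates leak with any other cause of a slow hematocrit
  decline (e.g. unrecorded bleeding in the other direction, measurement
  drift); the exclusion cascade removes the identifiable offenders only.
* Patients with a *rising* hematocrit land in the top quartile; whether
  they are physiologically the highest-leak group is uncertain, and they
  inflate variance at the high end of the partial-effect curves.
* BSA is a crude stand-in for blood volume; sex- and habitus-dependent
  error propagates multiplicatively into the index.
* The 9-df analysis-of-deviance is conservative for monotone
  alternatives at moderate n (a few hundred events); decisive p-values
  should be expected only at cohort sizes in the thousands.
* Associations estimated here are not causal claims; the models adjust
  for measured severity and comorbidity only.
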