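# Methods

This note documents the models and procedures implemented in `phasorckm`,
the choices made where several defensible options existed, and what the
synthetic-data tests do and do not establish about real-data behavior.

## Phasor analysis of light-activity synchronization

Minute-level illuminance (lux) and activity intensity are first made
comparable: lux is capped at 10,000 lux (the circadian photic response
saturates far below outdoor daylight levels) and transformed as
`log10(min(lux, 10000) + 1)`; activity counts are transformed as
`log10(counts + 1)` with no cap. The `+1` offset keeps zeros finite. The log
base is cosmetic: per-day standardization makes any base change affine, and a
test verifies magnitude and acrophase are invariant to it in effect.

The record is segmented into consecutive 24-hour days aligned to the
midnight-anchored minute grid (NHANES-style minute files start at midnight;
the boundary is configurable only through the grid itself). Day-level QC:

* a day must retain at least `min_valid_fraction = 0.8` of valid minutes
  (default; a device-quality or nonwear flag supplies validity);
* invalid minutes of a surviving day are linearly interpolated *within the
  day before transformation* — zero-filling would inject spurious 24-h power
  at the gap frequency;
* a day with zero variance in either transformed signal (e.g. constant
  darkness) is rejected;
* a participant needs `min_days = 4` surviving days, else they are excluded
  with a logged reason.

Both QC thresholds are explicit configuration, not claims about any
particular study's criteria.

Each surviving day is standardized to zero mean, unit *population* variance.
For standardized signals the circular cross-correlation

    r(tau) = (1/N) * sum_t x(t) * y((t + tau) mod N)

is a true correlation coefficient at every lag (|r| <= 1 by Cauchy-Schwarz).
It is computed by FFT; a brute-force O(N^2) loop serves as the oracle in
tests (agreement < 1e-10).

The per-day correlation functions are averaged across days and the 24-h
Fourier component extracted:

    P = (2/N) * sum_tau r(tau) * exp(-i 2 pi tau / N).

By linearity this equals the mean of per-day phasors (tested to 1e-12);
a config switch computes one correlation function over the concatenated
record instead, reading off the component at the 24-h frequency.

* **Magnitude** `|P|`: the 2/N scaling is fixed so a perfectly phase-locked
  sinusoidal pair scores exactly 1. The hard upper bound for any |r| <= 1
  correlation function is 4/pi (the square-wave fundamental); the result
  object enforces it. Published phasor tables on real actigraphy sit well
  below 1 (log-transformed daylight curves are far from sinusoidal and days
  vary), so magnitudes are comparable only within a fixed normalization
  convention — ours is the sinusoid-equals-1 convention.
* **Acrophase** `-arg(P) * 24 / (2 pi)` hours, wrapped into (-12, 12].
  The sign convention is fixed so that *activity lagging light is positive*
  (evening preference); a lag-equivariance test (shifting activity by +k
  minutes adds +k/60 hours) pins the sign down rather than assuming it.

Exposure quartiles cut the per-participant magnitudes at the 25/50/75
percentiles (weighted percentiles when survey weights are supplied), using
the left-continuous step definition; ties at a cutpoint go to the lower
quartile, and Q1 is the lowest-magnitude (most disrupted) quarter.

## CKM staging

Stages follow the explicit rule set in the module docstring
(`phasorckm/staging.py`). Numerical choices:

* all printed thresholds are inclusive; the prediabetes fasting-glucose band
  is implemented as 100-124 mg/dL inclusive, *as printed* in the source
  criteria even though conventional usage is 100-125;
* whether antidiabetic therapy qualifies for stage-1 prediabetes (as printed)
  or should be reserved for diabetes is a documented switch
  (`rx_counts_as_prediabetes`, default true = as printed);
* eGFR uses the race-free CKD-EPI 2021 creatinine equation; KDIGO albuminuria
  boundaries 30 and 300 mg/g are inclusive in A2; the KDIGO prognosis matrix
  is transcribed in full and tested cell by cell;
* the "elevated 10-year CVD risk" arm of stage 3 is a pluggable boolean
  input with an always-false default — no specific risk equation is endorsed,
  and synthetic runs stay self-contained;
* missing data: a rule with missing inputs simply does not fire; a profile is
  unstageable only when nothing at or above the provisional stage could be
  evaluated at all. This mirrors an analytic exclusion for missing CKM data
  without over-excluding profiles whose missing fields could not change the
  answer. Monotone dominance (adding a risk factor never lowers the stage) is
  property-tested on 10,000 random profiles.

## Survey-weighted models

Point estimates are weighted maximum pseudo-likelihood estimates; all
variances are Taylor-linearized stratified-cluster sandwiches: per-PSU totals
of the weighted score contributions are centered within stratum and combined
with `n_h/(n_h - 1)` factors, wrapped in the inverse-information bread.
Confidence intervals use Student's t with the design degrees of freedom
(PSUs minus strata), matching R `survey` conventions. Strata reduced to a
single PSU by subsetting are treated as certainty units; in a full
user-supplied design they are an error by default.

* **Logistic**: statsmodels GLM (binomial, frequency weights) supplies the
  weighted MLE; the sandwich is computed from `w_i (y_i - p_i) x_i`. Perfect
  separation is flagged (infinite CI marker), not silently reported.
* **Cox**: the weighted partial likelihood with **Efron** handling of ties is
  implemented directly (follow-up in months makes ties the norm and Efron is
  the lower-bias choice). Newton-Raphson with step-halving; covariates are
  centered at weighted means. Efron-consistent score residuals (the weighted
  residuals sum exactly to the score, ~1e-13 at the optimum) feed the same
  stratified-cluster sandwich. Note that weighted Efron with integer weights
  is deliberately *not* identical to row replication — replication changes
  the tie multiplicity — matching the behavior of R's `survival`.
* **Reference level**: quartile Q4 (highest magnitude, best alignment), so
  Q1 coefficients contrast the most disrupted against the best aligned.
* **Outcomes**: all-cause mortality; cardiovascular mortality as a
  cause-specific hazard (non-CVD deaths censored; no competing-risks model);
  premature mortality defined as death before attained age 70, with follow-up
  administratively censored at the age-70 boundary and participants already
  70+ at baseline excluded. Censoring-at-70 (rather than merely redefining
  the event) is our documented choice: it keeps the risk set honest after
  the age at which the event is no longer possible.
* **Sequential adjustment**: Model 1 unadjusted; Model 2 adds age, sex, race,
  education, income; Model 3 adds smoking and alcohol; Model 4 adds
  hypertension and diabetes. Categorical covariates are dummy-coded with the
  first level as reference.
* **Splines**: restricted cubic splines in the truncated-power natural-spline
  basis, 4 knots at the 5/35/65/95 weighted percentiles by default (3 or 5
  knots supported); curves are normalized to ratio 1.0 at the weighted median
  magnitude with delta-method pointwise CIs; a Wald test on the nonlinear
  coefficients tests departure from log-linearity.
* **Predicted survival**: weighted Breslow (Efron-step) baseline cumulative
  hazard at the weighted-mean covariate profile; per-quartile curves
  `exp(-Lambda_0(t) e^eta)` truncated at the last event time.
* **Subgroups**: age bands 20-39 / 40-59 / >=60 (baseline age) and sex;
  the stratifying variable is dropped from its own subgroups' covariate set;
  subgroups with too few events are skipped with a log entry.

### Finite-sample calibration

Simulation at the generator defaults (n = 2000, ~210 deaths, 15 strata x
2 PSUs, log-uniform weights over 1-10) shows 95% CI coverage of roughly
94-96% for the logistic Q1 odds ratio and 93-96% for the Cox Q1 hazard
ratio. The mild Cox-side undercoverage is the familiar finite-cluster
behavior of sandwich-variance Wald intervals at a handful of events per PSU;
the design-df t-quantiles recover most, but not all, of it. Users analyzing
designs with few PSUs and rare outcomes should expect intervals on the
slightly narrow side.

## Synthetic data: what it emulates and what it does not

The actigraphy generator writes, on the transformed scale,
`activity = rho * profilez(t - lag) + (1 - rho) * noise`, where `profilez`
is the standardized transformed daily light template, then maps both signals
back to raw lux/counts so files are byte-compatible with real minute data.
The default light template is a truncated-cosine daylight curve (zero
overnight, 1,000-lux peak at 13:00), which exercises the saturating
transform; an exact-sinusoid-after-log template provides the magnitude-1
analytic oracle. Nonwear is injected as contiguous blocks (mean ~2 h) to
stress the valid-day rule the way device removal does, not as scattered
minutes.

The cohort generator draws magnitude ~ Normal(0.34, 0.11) truncated to
(0, 1], covariate marginals matching a middle-aged overweight US cohort
(mean age ~52, 49% male, hypertension 50%, diabetes 23%), an advanced-CKM
indicator from `logit P = -1.55 + beta * 1[Q1]` (baseline prevalence ~18%),
exponential survival with baseline hazard 0.0012/month, exponential
censoring at 0.008/month plus administrative censoring at 120 months
(median follow-up ~83 months), and a cause-split calibrated so the
cause-specific CVD hazard ratio is exactly the injected value. The design is
15 strata x 2 PSUs with log-uniform weights on (1, 10) — genuine design
effects (deff ~ 1.4) without pathological leverage. Default injected
effects are Q1-vs-Q4 OR 1.8 and HR 2.0.

Not emulated: multistage selection (weights are independent of outcomes, so
weighted analyses are consistent by construction rather than by successful
de-biasing), informative missingness, device artifacts beyond nonwear,
seasonal or weekday structure in light exposure, and measurement error in
the clinical inputs. Passing tests therefore demonstrate that the estimators
are correct *under their stated assumptions*, not that those assumptions
hold in any particular survey.

Problem sizes in the test suite and acceptance script (cohorts of 200-2000,
500 replicates for coverage, 7-9 day recordings) were chosen as the smallest
sizes at which the Monte-Carlo bands in the tests are comfortably stable.

## Degenerate inputs and numerical edges

* Cross-correlation inputs must be standardized to 1e-6; FFT round-off at
  |r| = 1 is clipped.
* A quartile level with no events is flagged non-estimable instead of being
  sent into a divergent fit; separation and NaN-poisoned Newton steps raise
  a typed convergence error that the tidy-table layer converts to NaN rows.
* Duplicate spline knots (degenerate exposure distributions) raise a
  knot-placement error; fewer than four distinct magnitudes raise a
  degenerate-grouping error.
* All generators are `numpy.random.Generator`-seeded; identical spec + seed
  is bit-identical, and the full pipeline writes byte-identical outputs on
  re-run (manifests contain no timestamps).

## Known limitations

* No competing-risks (Fine-Gray) model; CVD mortality is cause-specific only.
* No multiple imputation; missing clinical data lead to rule non-firing or
  exclusion, as described.
* The phasor magnitude scale is convention-bound (sinusoid = 1); absolute
  values are not comparable across normalization conventions used elsewhere.
* The 10-year CVD risk arm of stage 3 is inert unless the user supplies a
  precomputed risk flag.
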