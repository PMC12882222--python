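# phasorckm

Circadian light-activity alignment from wrist actigraphy, cardio-kidney-
metabolic (CKM) syndrome staging, and survey-weighted epidemiological models
— an end-to-end, reproducible pipeline for studying whether circadian
disruption is associated with advanced CKM syndrome and mortality in
population surveys.

## Who this is for

Epidemiologists and chronobiologists working with minute-level light (lux)
and activity recordings from population surveys (NHANES-style physical
activity monitor files), a participant-level clinical table, mortality
linkage, and complex survey design variables (weight / stratum / PSU). The
package also ships a first-class synthetic-data module so every stage can be
exercised — and its estimators validated against known ground truth —
without downloading any survey data.

## The method

**Phasor analysis.** Per participant, lux is saturated at 10,000 lux and
log-transformed (`log10(min(lux, 10^4) + 1)`); activity counts are
log-transformed. The record is cut into consecutive 24-h days, QC-filtered,
and each day standardized. The circular cross-correlation between light and
activity, `r(τ) = (1/N) Σ_t x(t) y((t+τ) mod N)`, is averaged over days and
its 24-hour Fourier component extracted:

```
P = (2/N) Σ_τ r(τ) exp(−i 2π τ / N)
```

The **phasor magnitude** |P| measures the strength and regularity of
light-activity coupling (a phase-locked sinusoidal pair scores exactly 1);
the **acrophase** −arg(P)·24/2π, in hours wrapped to (−12, 12], is the
timing offset of activity relative to light — positive means activity lags
light (evening preference). Participants are grouped into magnitude
quartiles, Q1 = most disrupted, Q4 = reference.

**CKM staging.** Deterministic rules assign stages 0–4 (stage 0 no risk
factors → stage 4 clinical CVD), including the race-free CKD-EPI 2021 eGFR
equation, KDIGO G×A risk categorization, and a harmonized metabolic-syndrome
rule; *advanced* CKM is stages 3–4. Every fired rule is recorded for audit.

**Survey models.** Weighted logistic regression (advanced CKM) and weighted
Cox proportional-hazards regression with Efron ties (all-cause,
cardiovascular, and premature — before age 70 — mortality), both with
Taylor-linearized stratified-cluster variance and design-df t intervals,
across four sequentially adjusted covariate sets; restricted cubic splines
for nonlinearity; age/sex-stratified refits; predicted survival curves from
the weighted Breslow baseline hazard.

## Worked example

```python
from phasorckm import (
    ActigraphySimSpec, simulate_actigraphy, segment_and_qc, compute_phasor,
    ClinicalProfile, ckm_stage,
    CohortSimSpec, simulate_cohort, SurveyDesign, weighted_logistic, weighted_cox,
)
from phasorckm.models import exposure_dummies

# 1. a week of actigraphy with known coupling 0.85 and a +1.5 h activity lag
rec = simulate_actigraphy(ActigraphySimSpec(
    n_days=7, coupling_rho=0.85, lag_hours=1.5, missing_fraction=0.05, seed=42))
res = compute_phasor(segment_and_qc(rec))
print(f"magnitude={res.magnitude:.3f}  acrophase={res.acrophase_hours:+.2f} h")
# magnitude=0.869  acrophase=+1.51 h      (one day lost to nonwear QC)

# 2. stage a clinical profile
st = ckm_stage(ClinicalProfile(sex="male", age=58, waist_cm=108, bmi=31.2,
                               fpg_mg_dl=112, triglycerides_mg_dl=180,
                               hypertension=True, scr_mg_dl=1.1, uacr_mg_g=22))
print(st.stage, st.advanced, st.qualifying_criteria)
# 2 False ['triglycerides_ge_135', 'hypertension', 'metabolic_syndrome']

# 3. survey-weighted Q1-vs-Q4 estimates on a cohort with injected OR 1.8 / HR 2.0
coh = simulate_cohort(CohortSimSpec(n=2000, seed=7))
df = coh.table.join(exposure_dummies(coh.table))
design = SurveyDesign.from_frame(df)
_, or_tab = weighted_logistic(df, "advanced_ckm", ["Q1", "Q2", "Q3"], [], design)
_, hr_tab = weighted_cox(df, "followup_months", "dead", ["Q1", "Q2", "Q3"], [], design)
print(or_tab.round(3)); print(hr_tab.round(3))
```

The tables print the per-quartile odds/hazard ratios with design-based 95%
CIs (reference Q4); for this seed the Q1 rows read `OR 1.537 (0.973–2.428)`
and `HR 1.924 (1.284–2.885)` — single-sample draws around the injected
truths of 1.8 and 2.0, with CIs that cover them.

The full pipeline (preprocess → phasor → staging → models → tables) runs
from one YAML config:

```bash
phasorckm run-all config.yaml --seed 7 --output-dir results/
```

producing the phasor table, staged cohort, step-by-step exclusion log,
forest-plot tables for all four outcomes across Models 1–4, spline and
survival curves, weighted descriptives, and a manifest — all byte-identical
on re-run with the same seed.

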