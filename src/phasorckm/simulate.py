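"""Synthetic actigraphy, clinical, survival, and survey-design generators.

Every downstream stage of the pipeline is exercisable against data with known
ground truth:

* :func:`simulate_actigraphy` produces minute-grid lux/activity recordings in
  which the activity rhythm is, on the transformed scale, a tunable mixture of
  the (standardized, lag-shifted) daily light profile and white noise.  The
  coupling strength and the lag are therefore known exactly, which gives the
  phasor pipeline an analytic oracle.
* :func:`simulate_cohort` produces a participant-level analysis table with a
  magnitude-quartile exposure, an advanced-CKM indicator drawn from a logistic
  model with a stated Q1 log-odds effect, exponential proportional-hazards
  survival with stated Q1 log-hazard effects, independent censoring, and a
  stratified two-PSU-per-stratum design with unequal (log-uniform) weights.
* :func:`profile_for_stage` / :func:`simulate_clinical` produce clinical
  profiles that deterministically stage to a requested CKM stage, so staging
  and the end-to-end pipeline can be validated without real laboratory data.

Default parameter values mirror the marginals of the study population they
emulate (mean age ~52 y, 49% male, hypertension 50%, diabetes 23%, advanced
CKM ~19%, ~110-month administrative follow-up ceiling with a median near
83 months).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import LightActivityRecording, MINUTES_PER_DAY, transform_light
from .phasor import assign_quartiles, wrap_hours

__all__ = [
    "ActigraphySimSpec",
    "CohortSimSpec",
    "SurveyCohort",
    "truncated_cosine_template",
    "sinusoid_template",
    "simulate_actigraphy",
    "simulate_cohort",
    "profile_for_stage",
    "simulate_clinical",
]


def truncated_cosine_template(
    minutes_per_day: int = MINUTES_PER_DAY,
    peak_lux: float = 1000.0,
    peak_hour: float = 13.0,
    daylight_hours: float = 14.0,
) -> np.ndarray:
    """Truncated-cosine daylight curve: zero overnight, cosine bump peaking at 13:00.

    The default peaks at 1,000 lux so the saturating light transform is
    exercised without being dominated by the ceiling.
    """
    t = np.arange(minutes_per_day) / minutes_per_day * 24.0
    phase = (t - peak_hour) * 2 * np.pi / (2 * daylight_hours)
    profile = peak_lux * np.cos(np.clip(phase, -np.pi / 2, np.pi / 2))
    profile[np.abs((t - peak_hour + 12) % 24 - 12) > daylight_hours / 2] = 0.0
    return np.maximum(profile, 0.0)


def sinusoid_template(
    minutes_per_day: int = MINUTES_PER_DAY,
    mean_lux: float = 500.0,
    amplitude_lux: float = 499.0,
    peak_hour: float = 13.0,
) -> np.ndarray:
    """Pure 24-h sinusoidal lux template (analytic oracle for phasor tests)."""
    t = np.arange(minutes_per_day) / minutes_per_day * 24.0
    return mean_lux + amplitude_lux * np.cos((t - peak_hour) * 2 * np.pi / 24.0)


def log_sinusoid_template(
    minutes_per_day: int = MINUTES_PER_DAY,
    log_mean: float = 1.5,
    log_amplitude: float = 1.2,
    peak_hour: float = 13.0,
) -> np.ndarray:
    """Lux template whose *log-transformed* profile is a pure 24-h sinusoid.

    ``lux = 10^(log_mean + log_amplitude * cos(...)) - 1`` inverts the light
    transform exactly, so with full coupling and no noise the standardized
    transformed signals are sinusoids and the phasor magnitude attains its
    theoretical value of 1 (the analytic oracle for the full pipeline).
    """
    t = np.arange(minutes_per_day) / minutes_per_day * 24.0
    logv = log_mean + log_amplitude * np.cos((t - peak_hour) * 2 * np.pi / 24.0)
    return np.power(10.0, logv) - 1.0


@dataclass
class ActigraphySimSpec:
    """Ground-truth description of one simulated actigraphy recording.

    ``coupling_rho`` is the fraction of the transformed activity signal taken
    from the (standardized, lag-shifted) transformed light template;
    ``1 - coupling_rho`` multiplies independent white noise.  ``lag_hours`` is
    the offset of the activity rhythm *after* the light rhythm (positive =
    activity lags light), wrapped into (-12, 12].
    """

    n_days: int = 7
    minutes_per_day: int = MINUTES_PER_DAY
    coupling_rho: float = 0.8
    lag_hours: float = 0.0
    light_profile: np.ndarray | None = None
    noise_sd_light: float = 0.15
    noise_sd_activity: float = 1.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.coupling_rho <= 1.0:
            raise ValueError("coupling_rho must lie in [0, 1]")
        if not -24.0 < self.lag_hours < 24.0:
            raise ValueError("lag_hours must lie within a 24-h span")
        self.lag_hours = wrap_hours(self.lag_hours)
        if self.minutes_per_day < 24:
            raise ValueError("minutes_per_day must be >= 24")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.noise_sd_light < 0 or self.noise_sd_activity < 0:
            raise ValueError("noise SDs must be nonnegative")
        if self.light_profile is None:
            self.light_profile = truncated_cosine_template(self.minutes_per_day)
        self.light_profile = np.asarray(self.light_profile, dtype=float)
        if len(self.light_profile) != self.minutes_per_day:
            raise ValueError("light_profile must have length minutes_per_day")
        if np.any(self.light_profile < 0):
            raise ValueError("light_profile must be nonnegative")


def _nonwear_mask(n: int, fraction: float, rng: np.random.Generator,
                  mean_block: float = 120.0) -> np.ndarray:
    """Contiguous nonwear blocks (device removal) totalling ~``fraction`` of minutes."""
    mask = np.zeros(n, dtype=bool)
    target = int(round(fraction * n))
    guard = 0
    while mask.sum() < target and guard < 10_000:
        guard += 1
        length = max(10, int(rng.exponential(mean_block)))
        start = int(rng.integers(0, n))
        mask[start:start + length] = True
    return mask


def simulate_actigraphy(spec: ActigraphySimSpec) -> LightActivityRecording:
    """Generate a minute-grid recording with known coupling and lag.

    On the transformed (log-lux / log-counts) scale,

        activity_t(t) = rho * profilez(t - lag) + (1 - rho) * eps(t),

    where ``profilez`` is the standardized transformed light template and
    ``eps`` is white noise with SD ``noise_sd_activity``.  The transformed
    signals are mapped back to the raw scale (inverting the log transforms)
    so the output is byte-compatible with real minute files; downstream
    per-day standardization makes the affine back-mapping irrelevant to the
    phasor.  Identical spec + seed gives bit-identical output.
    """
    rng = np.random.default_rng(spec.seed)
    m, nd = spec.minutes_per_day, spec.n_days
    n = m * nd

    template_t = transform_light(spec.light_profile)
    if template_t.std() < 1e-12:
        raise ValueError("light_profile has zero variance after transform")
    profilez = (template_t - template_t.mean()) / template_t.std()

    lag_minutes = int(round(spec.lag_hours * m / 24.0))
    shifted = np.roll(profilez, lag_minutes)  # activity peaks lag_minutes after light

    light_t = np.tile(template_t, nd) + spec.noise_sd_light * rng.standard_normal(n)
    noise = spec.noise_sd_activity * rng.standard_normal(n)
    activity_t = spec.coupling_rho * np.tile(shifted, nd) + (1.0 - spec.coupling_rho) * noise

    # invert transforms back to raw scale (clip the light ceiling at saturation)
    lux = np.clip(np.power(10.0, light_t) - 1.0, 0.0, None)
    # map standardized-scale activity onto a plausible log10-counts scale
    counts = np.clip(np.power(10.0, 1.5 + 0.6 * activity_t) - 1.0, 0.0, None)

    valid = np.ones(n, dtype=bool)
    if spec.missing_fraction > 0:
        nonwear = _nonwear_mask(n, spec.missing_fraction, rng)
        valid[nonwear] = False
        lux[nonwear] = 0.0
        counts[nonwear] = 0.0

    return LightActivityRecording(
        participant_id=f"sim-{spec.seed}",
        lux=lux, activity=counts, valid=valid,
        minutes_per_day=m,
    )


# ---------------------------------------------------------------------------
# Cohort simulation: exposure, covariates, outcomes, survey design
# ---------------------------------------------------------------------------

RACE_LEVELS = ["mexican_american", "hispanic", "nh_white", "nh_black", "other"]
RACE_PROBS = [0.136, 0.102, 0.418, 0.250, 0.094]
EDUCATION_LEVELS = ["less_than_hs", "hs_graduate", "some_college", "college_plus"]
EDUCATION_PROBS = [0.231, 0.230, 0.315, 0.224]
INCOME_LEVELS = ["lt_20k", "20_45k", "45_75k", "75k_plus"]
INCOME_PROBS = [0.229, 0.344, 0.178, 0.249]
ALCOHOL_LEVELS = ["none", "lt_weekly", "weekly_to_daily", "daily_plus"]
ALCOHOL_PROBS = [0.383, 0.353, 0.228, 0.036]


@dataclass
class CohortSimSpec:
    """Ground-truth description of a simulated survey cohort.

    Effects are log-scale contrasts of the lowest magnitude quartile (Q1)
    against the reference quartile Q4.  ``baseline_hazard`` and
    ``censor_rate`` are per-month exponential rates; follow-up is
    administratively censored at 120 months.
    """

    n: int = 2000
    beta_advanced: float = math.log(1.8)
    log_hr_allcause: float = math.log(2.0)
    log_hr_cvd: float = math.log(2.0)
    baseline_hazard: float = 0.0012
    censor_rate: float = 0.008
    n_strata: int = 15
    psus_per_stratum: int = 2
    weight_range: tuple = (1.0, 10.0)
    baseline_advanced_logit: float = -1.55
    cvd_death_fraction: float = 0.25
    admin_censor_months: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 4 * self.n_strata * self.psus_per_stratum:
            raise ValueError("n must be >= 4 * n_strata * psus_per_stratum")
        if self.psus_per_stratum < 2:
            raise ValueError("every stratum needs >= 2 PSUs for variance estimation")
        if self.baseline_hazard <= 0 or self.censor_rate <= 0:
            raise ValueError("rates must be positive")
        lo, hi = self.weight_range
        if lo <= 0 or hi < lo:
            raise ValueError("weights must be positive with max >= min")


@dataclass
class SurveyCohort:
    """Analysis table plus the ground-truth parameters that generated it."""

    table: pd.DataFrame
    truth: dict
    weight_col: str = "weight"
    stratum_col: str = "stratum"
    psu_col: str = "psu"


def _draw_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    age = np.clip(rng.normal(51.8, 16.5, n), 20.0, 85.0)
    return pd.DataFrame({
        "age": age,
        "sex": rng.choice(["male", "female"], n, p=[0.493, 0.507]),
        "race": rng.choice(RACE_LEVELS, n, p=RACE_PROBS),
        "education": rng.choice(EDUCATION_LEVELS, n, p=EDUCATION_PROBS),
        "income": rng.choice(INCOME_LEVELS, n, p=INCOME_PROBS),
        "smoking": rng.random(n) < 0.175,
        "alcohol": rng.choice(ALCOHOL_LEVELS, n, p=ALCOHOL_PROBS),
        "hypertension": rng.random(n) < 0.503,
        "diabetes": rng.random(n) < 0.228,
    })


def _survey_design(n: int, spec: CohortSimSpec, rng: np.random.Generator) -> pd.DataFrame:
    strata = np.repeat(np.arange(spec.n_strata), math.ceil(n / spec.n_strata))[:n]
    psu = rng.integers(0, spec.psus_per_stratum, n)
    lo, hi = spec.weight_range
    weight = np.exp(rng.uniform(math.log(lo), math.log(hi), n))
    return pd.DataFrame({"stratum": strata, "psu": psu, "weight": weight})


def simulate_cohort(spec: CohortSimSpec) -> SurveyCohort:
    """Simulate a survey cohort with known Q1-vs-Q4 effects.

    Magnitude is drawn Normal(0.34, 0.11) truncated to (0.01, 1); quartiles are
    computed on the realized values.  The advanced-CKM indicator follows
    ``logit P = baseline_advanced_logit + beta_advanced * 1[Q1]``.  Death times
    are exponential with hazard ``baseline_hazard * exp(log_hr_allcause*1[Q1])``;
    given death, the cause is cardiovascular with a Q1-dependent probability
    calibrated so the cause-specific CVD hazard ratio is exactly
    ``exp(log_hr_cvd)``.  Censoring is independent exponential plus an
    administrative ceiling.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    mag = np.clip(rng.normal(0.34, 0.11, n), 0.01, 1.0)
    quartile, cuts = assign_quartiles(mag)
    q1 = (quartile == 1).astype(float)

    cov = _draw_covariates(n, rng)
    design = _survey_design(n, spec, rng)

    logit = spec.baseline_advanced_logit + spec.beta_advanced * q1
    advanced = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    hazard = spec.baseline_hazard * np.exp(spec.log_hr_allcause * q1)
    t_death = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / spec.censor_rate, n)
    followup = np.minimum(np.minimum(t_death, t_cens), spec.admin_censor_months)
    dead = t_death <= np.minimum(t_cens, spec.admin_censor_months)

    # cause-specific CVD hazard ratio is exact when P(CVD | death) scales with
    # exp(log_hr_cvd - log_hr_allcause) in Q1
    p_cvd = np.where(
        q1 > 0,
        min(1.0, spec.cvd_death_fraction * math.exp(spec.log_hr_cvd - spec.log_hr_allcause)),
        spec.cvd_death_fraction,
    )
    cvd_death = dead & (rng.random(n) < p_cvd)

    table = pd.concat([
        pd.DataFrame({
            "participant_id": [f"p{i:05d}" for i in range(n)],
            "magnitude": mag,
            "quartile": quartile.astype(int),
        }),
        cov,
        pd.DataFrame({
            "advanced_ckm": advanced,
            "followup_months": followup,
            "dead": dead,
            "cvd_death": cvd_death,
        }),
        design,
    ], axis=1)
    table["age_at_exit"] = table["age"] + table["followup_months"] / 12.0

    truth = {
        "beta_advanced": spec.beta_advanced,
        "log_hr_allcause": spec.log_hr_allcause,
        "log_hr_cvd": spec.log_hr_cvd,
        "quartile_cuts": list(cuts),
    }
    return SurveyCohort(table=table, truth=truth)


# ---------------------------------------------------------------------------
# Clinical profiles spanning the CKM stages
# ---------------------------------------------------------------------------

def _base_profile(rng: np.random.Generator) -> dict:
    """A metabolically healthy adult profile (stages to 0 when left unmodified)."""
    sex = "female" if rng.random() < 0.5 else "male"
    return {
        "sex": sex,
        "age": float(rng.uniform(25, 75)),
        "waist_cm": float(rng.uniform(70, 86) if sex == "female" else rng.uniform(80, 100)),
        "bmi": float(rng.uniform(19.0, 24.5)),
        "fpg_mg_dl": float(rng.uniform(75, 98)),
        "hba1c_pct": float(rng.uniform(4.8, 5.5)),
        "on_antidiabetic_rx": False,
        "triglycerides_mg_dl": float(rng.uniform(60, 125)),
        "hdl_mg_dl": float(rng.uniform(55, 80)),
        "sbp": float(rng.uniform(100, 124)),
        "dbp": float(rng.uniform(60, 79)),
        "on_antihypertensive_rx": False,
        "hypertension": False,
        "diabetes": False,
        "scr_mg_dl": float(rng.uniform(0.6, 0.9)),
        "uacr_mg_g": float(rng.uniform(2, 25)),
        "cvd_history": False,
        "ten_year_cvd_risk_elevated": False,
    }


def profile_for_stage(
    stage: int,
    rng: np.random.Generator | int = 0,
    sex: str | None = None,
    age: float | None = None,
) -> dict:
    """A clinical profile dict that deterministically stages to ``stage``.

    Used both as a test fixture factory and by the synthetic pipeline to turn
    a drawn CKM stage into a concrete clinical row.  ``sex``/``age`` override
    the drawn demographics (the stage guarantee holds for any adult age).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    p = _base_profile(rng)
    if sex is not None:
        if sex != p["sex"]:
            p["sex"] = sex
            # waist draws are sex-specific; redraw below the sex's threshold
            p["waist_cm"] = float(rng.uniform(70, 86) if sex == "female"
                                  else rng.uniform(80, 100))
    if age is not None:
        p["age"] = float(age)
    if stage == 0:
        return p
    # stage >= 1: overweight (the study population is BMI >= 25 anyway)
    p["bmi"] = float(rng.uniform(25.0, 38.0))
    p["waist_cm"] = float(rng.uniform(90, 120) if p["sex"] == "male" else rng.uniform(80, 110))
    if stage == 1:
        if rng.random() < 0.5:
            p["fpg_mg_dl"] = float(rng.uniform(100, 124))  # prediabetes band
        return p
    if stage == 2:
        pick = rng.integers(0, 3)
        if pick == 0:
            p["triglycerides_mg_dl"] = float(rng.uniform(135, 400))
        elif pick == 1:
            p["hypertension"] = True
        else:
            p["diabetes"] = True
            p["on_antidiabetic_rx"] = True
        return p
    if stage == 3:
        # very-high-risk CKD via KDIGO: severe albuminuria plus reduced eGFR
        p["uacr_mg_g"] = float(rng.uniform(310, 1500))
        p["scr_mg_dl"] = float(rng.uniform(1.8, 2.6))  # guarantees eGFR < 60 for adults
        return p
    if stage == 4:
        p["cvd_history"] = True
        if rng.random() < 0.5:
            p["hypertension"] = True
        return p
    raise ValueError("stage must be in 0..4")


def simulate_clinical(
    stages: np.ndarray,
    seed: int = 0,
    sex: np.ndarray | None = None,
    age: np.ndarray | None = None,
) -> pd.DataFrame:
    """Clinical table whose rows stage (deterministically) to ``stages``."""
    rng = np.random.default_rng(seed)
    stages = np.asarray(stages)
    rows = [
        profile_for_stage(
            int(s), rng,
            sex=None if sex is None else sex[i],
            age=None if age is None else float(age[i]),
        )
        for i, s in enumerate(stages)
    ]
    return pd.DataFrame(rows)
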