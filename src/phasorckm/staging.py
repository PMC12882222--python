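"""Cardio-kidney-metabolic (CKM) syndrome staging, stages 0-4.

The CKM construct grades the joint burden of metabolic risk, chronic kidney
disease and cardiovascular disease on an ordinal 0-4 scale:

* **Stage 0** - no risk factors: waist circumference below 88 cm (women) /
  102 cm (men) and no higher-stage criterion met.
* **Stage 1** - excess adiposity or prediabetes: BMI >= 25 kg/m2, elevated
  waist circumference, or prediabetes (fasting glucose 100-124 mg/dL,
  HbA1c 5.7-6.4%, or antidiabetic therapy).
* **Stage 2** - manifest metabolic risk factors (triglycerides >= 135 mg/dL,
  hypertension, diabetes, or metabolic syndrome) or moderate/high-risk CKD.
* **Stage 3** - very-high-risk CKD or elevated 10-year CVD risk.
* **Stage 4** - clinical cardiovascular disease.

"Advanced" CKM is the stage 3-4 dichotomy used as the cross-sectional outcome.
CKD risk is graded on the KDIGO heat map from the eGFR category (G1-G5,
CKD-EPI 2021 race-free creatinine equation) crossed with the albuminuria
category (A1-A3 from the urine albumin-to-creatinine ratio).

All thresholds are inclusive as printed above (the prediabetes band is
implemented as 100-124 mg/dL inclusive, which is the rule as stated even
though conventional usage is 100-125).  The stage is the maximum over all
satisfied rules; a rule whose inputs are missing simply does not fire, and a
profile is "unstageable" only when nothing at or above the provisional stage
could be evaluated at all.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ClinicalProfile",
    "CKMStage",
    "UnstageableError",
    "egfr_ckd_epi_2021",
    "kdigo_g_stage",
    "kdigo_a_stage",
    "kdigo_risk",
    "has_metabolic_syndrome",
    "ckm_stage",
    "stage_dataframe",
]

WAIST_THRESHOLD_CM = {"female": 88.0, "male": 102.0}


class UnstageableError(ValueError):
    """Profile has too little data to assign any CKM stage."""


@dataclass
class ClinicalProfile:
    """All clinical inputs to CKM staging.  Optional fields may be None (missing)."""

    sex: str
    age: float
    waist_cm: float | None = None
    bmi: float | None = None
    fpg_mg_dl: float | None = None
    hba1c_pct: float | None = None
    on_antidiabetic_rx: bool = False
    triglycerides_mg_dl: float | None = None
    hdl_mg_dl: float | None = None
    sbp: float | None = None
    dbp: float | None = None
    on_antihypertensive_rx: bool = False
    hypertension: bool | None = None
    diabetes: bool | None = None
    scr_mg_dl: float | None = None
    uacr_mg_g: float | None = None
    cvd_history: bool | None = None
    ten_year_cvd_risk_elevated: bool | None = None

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValueError("sex must be 'male' or 'female'")
        if self.waist_cm is not None and self.waist_cm <= 0:
            raise ValueError("waist_cm must be positive")
        if self.bmi is not None and self.bmi <= 0:
            raise ValueError("bmi must be positive")
        for name in ("fpg_mg_dl", "hba1c_pct", "triglycerides_mg_dl", "hdl_mg_dl",
                     "sbp", "dbp", "scr_mg_dl", "uacr_mg_g"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class CKMStage:
    """Staging outcome: ordinal stage, advanced dichotomy, and the rules that fired."""

    stage: int
    advanced: bool
    qualifying_criteria: list

    def __post_init__(self) -> None:
        if self.stage not in (0, 1, 2, 3, 4):
            raise ValueError("stage must be in 0..4")
        if self.advanced != (self.stage in (3, 4)):
            raise ValueError("advanced must equal stage in {3, 4}")


# ---------------------------------------------------------------------------
# Kidney function: eGFR, KDIGO categories, KDIGO risk matrix
# ---------------------------------------------------------------------------

def egfr_ckd_epi_2021(scr_mg_dl: float, age: float, sex: str) -> float:
    """Estimated GFR (mL/min/1.73 m2), CKD-EPI 2021 race-free creatinine equation.

    eGFR = 142 * min(Scr/k, 1)^a * max(Scr/k, 1)^-1.200 * 0.9938^age
           * 1.012 [if female],
    with k = 0.7 (female) / 0.9 (male) and a = -0.241 (female) / -0.302 (male).
    """
    if scr_mg_dl <= 0:
        raise ValueError("serum creatinine must be positive")
    if age < 18:
        raise ValueError("equation is validated for adults (age >= 18)")
    if sex == "female":
        k, a, s = 0.7, -0.241, 1.012
    elif sex == "male":
        k, a, s = 0.9, -0.302, 1.0
    else:
        raise ValueError("sex must be 'male' or 'female'")
    r = scr_mg_dl / k
    return 142.0 * min(r, 1.0) ** a * max(r, 1.0) ** -1.200 * 0.9938 ** age * s


def kdigo_g_stage(egfr: float) -> str:
    """KDIGO eGFR category G1..G5 (G1 >= 90 down to G5 < 15; boundaries inclusive upward)."""
    if egfr is None or not np.isfinite(egfr) or egfr < 0:
        raise ValueError("egfr must be finite and nonnegative")
    if egfr >= 90:
        return "G1"
    if egfr >= 60:
        return "G2"
    if egfr >= 45:
        return "G3a"
    if egfr >= 30:
        return "G3b"
    if egfr >= 15:
        return "G4"
    return "G5"


def kdigo_a_stage(uacr_mg_g: float) -> str:
    """KDIGO albuminuria category from UACR: A1 < 30, A2 30-300 (inclusive), A3 > 300."""
    if uacr_mg_g is None or not np.isfinite(uacr_mg_g) or uacr_mg_g < 0:
        raise ValueError("uacr must be finite and nonnegative")
    if uacr_mg_g < 30:
        return "A1"
    if uacr_mg_g <= 300:
        return "A2"
    return "A3"


#: The KDIGO 2012 prognosis heat map (G category x A category).
KDIGO_RISK_MATRIX = {
    ("G1", "A1"): "low", ("G1", "A2"): "moderate", ("G1", "A3"): "high",
    ("G2", "A1"): "low", ("G2", "A2"): "moderate", ("G2", "A3"): "high",
    ("G3a", "A1"): "moderate", ("G3a", "A2"): "high", ("G3a", "A3"): "very_high",
    ("G3b", "A1"): "high", ("G3b", "A2"): "very_high", ("G3b", "A3"): "very_high",
    ("G4", "A1"): "very_high", ("G4", "A2"): "very_high", ("G4", "A3"): "very_high",
    ("G5", "A1"): "very_high", ("G5", "A2"): "very_high", ("G5", "A3"): "very_high",
}


def kdigo_risk(g_stage: str, a_stage: str) -> str:
    """KDIGO CKD prognosis class: low / moderate / high / very_high."""
    try:
        return KDIGO_RISK_MATRIX[(g_stage, a_stage)]
    except KeyError:
        raise ValueError(f"undefined KDIGO cell ({g_stage}, {a_stage})") from None


# ---------------------------------------------------------------------------
# Metabolic syndrome and the stage rules
# ---------------------------------------------------------------------------

def _tri(x):
    """Missing-tolerant truth value: True / False / None."""
    return None if x is None else bool(x)


def has_metabolic_syndrome(profile: ClinicalProfile) -> bool | None:
    """Harmonized ATP-III metabolic syndrome: >= 3 of 5 components.

    Components (thresholds inclusive): elevated waist circumference
    (>= 88/102 cm F/M), triglycerides >= 150 mg/dL, low HDL (< 50/40 F/M),
    blood pressure >= 130/85 mmHg or antihypertensive therapy, fasting glucose
    >= 100 mg/dL or antidiabetic therapy.  Returns None when missing
    components leave the >= 3 count undecidable.
    """
    p = profile
    wc = None if p.waist_cm is None else p.waist_cm >= WAIST_THRESHOLD_CM[p.sex]
    tg = None if p.triglycerides_mg_dl is None else p.triglycerides_mg_dl >= 150.0
    hdl_cut = 50.0 if p.sex == "female" else 40.0
    hdl = None if p.hdl_mg_dl is None else p.hdl_mg_dl < hdl_cut
    if p.on_antihypertensive_rx:
        bp = True
    elif p.sbp is None or p.dbp is None:
        bp = None
    else:
        bp = p.sbp >= 130.0 or p.dbp >= 85.0
    if p.on_antidiabetic_rx:
        glu = True
    elif p.fpg_mg_dl is None:
        glu = None
    else:
        glu = p.fpg_mg_dl >= 100.0
    comps = [wc, tg, hdl, bp, glu]
    n_true = sum(c is True for c in comps)
    n_unknown = sum(c is None for c in comps)
    if n_true >= 3:
        return True
    if n_true + n_unknown < 3:
        return False
    return None


def _kdigo_risk_or_none(p: ClinicalProfile) -> str | None:
    if p.scr_mg_dl is None or p.uacr_mg_g is None:
        return None
    egfr = egfr_ckd_epi_2021(p.scr_mg_dl, max(p.age, 18.0), p.sex)
    return kdigo_risk(kdigo_g_stage(egfr), kdigo_a_stage(p.uacr_mg_g))


def _stage_rules(p: ClinicalProfile, rx_counts_as_prediabetes: bool = True) -> dict:
    """Evaluate every stage rule tri-state; keys are (stage, rule_id)."""
    risk = _kdigo_risk_or_none(p)
    prediab_parts = [
        None if p.fpg_mg_dl is None else 100.0 <= p.fpg_mg_dl <= 124.0,
        None if p.hba1c_pct is None else 5.7 <= p.hba1c_pct <= 6.4,
        bool(p.on_antidiabetic_rx) if rx_counts_as_prediabetes else False,
    ]
    if any(x is True for x in prediab_parts):
        prediabetes = True
    elif all(x is False for x in prediab_parts):
        prediabetes = False
    else:
        prediabetes = None
    wc_high = (None if p.waist_cm is None
               else p.waist_cm >= WAIST_THRESHOLD_CM[p.sex])
    return {
        (4, "cvd_history"): _tri(p.cvd_history),
        (3, "very_high_risk_ckd"): None if risk is None else risk == "very_high",
        (3, "elevated_10yr_cvd_risk"): _tri(p.ten_year_cvd_risk_elevated),
        (2, "triglycerides_ge_135"): (None if p.triglycerides_mg_dl is None
                                      else p.triglycerides_mg_dl >= 135.0),
        (2, "hypertension"): _tri(p.hypertension),
        (2, "diabetes"): _tri(p.diabetes),
        (2, "metabolic_syndrome"): has_metabolic_syndrome(p),
        (2, "moderate_or_high_risk_ckd"): (None if risk is None
                                           else risk in ("moderate", "high")),
        (1, "bmi_ge_25"): None if p.bmi is None else p.bmi >= 25.0,
        (1, "waist_elevated"): wc_high,
        (1, "prediabetes"): prediabetes,
        (0, "waist_below_threshold"): None if wc_high is None else not wc_high,
    }


def ckm_stage(profile: ClinicalProfile, rx_counts_as_prediabetes: bool = True) -> CKMStage:
    """Assign the CKM stage: the maximum stage whose rule set is satisfied.

    A rule with missing inputs does not fire.  When no rule fires and nothing
    at or above the provisional stage (including the stage-0 waist criterion)
    is evaluable, the profile is unstageable and :class:`UnstageableError` is
    raised -- mirroring the analytic exclusion of participants with missing
    CKM data.
    """
    rules = _stage_rules(profile, rx_counts_as_prediabetes)
    fired = [(s, rid) for (s, rid), v in rules.items() if v is True and s > 0]
    stage = max((s for s, _ in fired), default=0)
    if stage == 0:
        evaluable = [v for (s, _), v in rules.items() if v is not None]
        if not evaluable:
            raise UnstageableError("no CKM stage rule could be evaluated")
        if rules[(0, "waist_below_threshold")] is None and all(
            v is None for (s, _), v in rules.items() if s > 0
        ):
            raise UnstageableError("no CKM stage rule could be evaluated")
        criteria = ["waist_below_threshold"] if rules[(0, "waist_below_threshold")] else []
    else:
        criteria = [rid for (s, rid) in fired if s == stage]
    return CKMStage(stage=stage, advanced=stage >= 3, qualifying_criteria=criteria)


# ---------------------------------------------------------------------------
# DataFrame front-end
# ---------------------------------------------------------------------------

PROFILE_FIELDS = [f for f in ClinicalProfile.__dataclass_fields__]


def stage_dataframe(df: pd.DataFrame, rx_counts_as_prediabetes: bool = True) -> pd.DataFrame:
    """Stage every row of a clinical table.

    Adds ``ckm_stage`` (float, NaN when unstageable), ``advanced_ckm`` (boolean,
    NA when unstageable) and ``ckm_criteria`` (semicolon-joined audit trail of
    the fired rules).  Column names must match :class:`ClinicalProfile` fields;
    extra columns pass through untouched.
    """
    out = df.copy()
    stages, advanced, criteria = [], [], []
    for _, row in df.iterrows():
        kwargs = {}
        for f in PROFILE_FIELDS:
            if f in row.index:
                v = row[f]
                kwargs[f] = None if (v is None or (isinstance(v, float) and math.isnan(v))) else v
        try:
            res = ckm_stage(ClinicalProfile(**kwargs), rx_counts_as_prediabetes)
            stages.append(float(res.stage))
            advanced.append(res.advanced)
            criteria.append(";".join(res.qualifying_criteria))
        except UnstageableError:
            stages.append(float("nan"))
            advanced.append(pd.NA)
            criteria.append("unstageable")
    out["ckm_stage"] = stages
    out["advanced_ckm"] = pd.array(advanced, dtype="boolean")
    out["ckm_criteria"] = criteria
    return out
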