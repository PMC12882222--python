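"""Sequential adjustment models and subgroup (stratified) fits.

Four nested covariate sets are fitted for every outcome:

* Model 1 - unadjusted (exposure quartiles only);
* Model 2 - + age, sex, race, education, household income;
* Model 3 - + smoking status, weekly alcohol consumption;
* Model 4 - + hypertension, diabetes.

The exposure is the phasor-magnitude quartile with Q4 (highest magnitude,
best light-activity alignment) as the reference level, so Q1 contrasts the
most circadian-disrupted quarter against the best-aligned quarter.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .survey import SeparationWarningError, SurveyDesign, weighted_logistic
from .survival import premature_death_model, weighted_cox

logger = logging.getLogger(__name__)

__all__ = [
    "MODEL_COVARIATES",
    "exposure_dummies",
    "build_design",
    "fit_sequential_models",
    "stratified_fits",
    "AGE_BANDS",
]

MODEL_COVARIATES = {
    1: [],
    2: ["age", "sex", "race", "education", "income"],
    3: ["age", "sex", "race", "education", "income", "smoking", "alcohol"],
    4: ["age", "sex", "race", "education", "income", "smoking", "alcohol",
        "hypertension", "diabetes"],
}

#: Baseline-age subgroup bands used in stratified analyses.
AGE_BANDS = {"20-39": (20.0, 40.0), "40-59": (40.0, 60.0), ">=60": (60.0, np.inf)}

_CATEGORICAL = {"sex", "race", "education", "income", "alcohol"}

_SURVIVAL_COLS = ["followup_months", "dead", "cvd_death", "age", "age_at_exit"]


def exposure_dummies(df: pd.DataFrame, quartile_col: str = "quartile",
                     reference: int = 4) -> pd.DataFrame:
    """Indicator columns Q1..Q3 with Q4 (highest magnitude) as reference."""
    out = pd.DataFrame(index=df.index)
    for q in (1, 2, 3, 4):
        if q == reference:
            continue
        out[f"Q{q}"] = (df[quartile_col] == q).astype(float)
    return out


def build_design(df: pd.DataFrame, covariates: list) -> pd.DataFrame:
    """Numeric design columns for a covariate list (categoricals dummy-coded)."""
    pieces = []
    for c in covariates:
        if c in _CATEGORICAL:
            d = pd.get_dummies(df[c].astype(str), prefix=c, drop_first=True, dtype=float)
            pieces.append(d)
        else:
            pieces.append(df[c].astype(float).rename(c).to_frame())
    if not pieces:
        return pd.DataFrame(index=df.index)
    out = pd.concat(pieces, axis=1)
    # a covariate level absent from (or universal in) a subgroup is dropped
    keep = out.std(axis=0) > 0
    return out.loc[:, keep]


def _one_fit(
    df: pd.DataFrame,
    design: SurveyDesign,
    outcome_kind: str,
    quartile_col: str,
    covariates: list,
) -> pd.DataFrame:
    exp = exposure_dummies(df, quartile_col)
    cov = build_design(df, covariates)
    exposure_cols = exp.columns.tolist()
    cov_cols = cov.columns.tolist()

    if outcome_kind == "advanced_ckm":
        frame = pd.concat(
            [df[["advanced_ckm"]].reset_index(drop=True),
             exp.reset_index(drop=True), cov.reset_index(drop=True)], axis=1,
        )
        frame["advanced_ckm"] = frame["advanced_ckm"].astype(float)
        try:
            _, table = weighted_logistic(frame, "advanced_ckm", exposure_cols, cov_cols, design)
        except SeparationWarningError as exc:
            logger.warning("logistic fit flagged: %s", exc)
            table = pd.DataFrame({"term": exposure_cols, "OR": np.nan, "ci_lower": np.nan,
                                  "ci_upper": np.nan, "se_log": np.nan,
                                  "n": len(frame), "events": np.nan})
        table = table.rename(columns={"OR": "estimate"})
        table["measure"] = "OR"
        return table

    frame = pd.concat(
        [df[_SURVIVAL_COLS].reset_index(drop=True),
         exp.reset_index(drop=True), cov.reset_index(drop=True)], axis=1,
    )
    frame = frame.loc[:, ~frame.columns.duplicated()]  # 'age' is both outcome input and covariate
    if outcome_kind == "all_cause":
        _, table = weighted_cox(frame, "followup_months", "dead", exposure_cols, cov_cols, design)
    elif outcome_kind == "cvd":
        _, table = weighted_cox(frame, "followup_months", "cvd_death", exposure_cols, cov_cols, design)
    elif outcome_kind == "premature":
        _, table = premature_death_model(frame, exposure_cols, cov_cols, design)
    else:
        raise ValueError(f"unknown outcome {outcome_kind!r}")
    table = table.rename(columns={"HR": "estimate"})
    table["measure"] = "HR"
    return table


def fit_sequential_models(
    df: pd.DataFrame,
    design: SurveyDesign,
    outcome_kind: str,
    models=(1, 2, 3, 4),
    quartile_col: str = "quartile",
) -> pd.DataFrame:
    """Forest-table content: Q1-Q3 vs Q4 estimates across Models 1-4.

    ``outcome_kind`` is one of ``advanced_ckm`` (weighted logistic OR),
    ``all_cause``, ``cvd``, ``premature`` (weighted Cox HR).
    """
    out = []
    for m in models:
        table = _one_fit(df, design, outcome_kind, quartile_col, MODEL_COVARIATES[m])
        table.insert(0, "model", m)
        table.insert(1, "outcome", outcome_kind)
        out.append(table)
    return pd.concat(out, ignore_index=True)


def stratified_fits(
    df: pd.DataFrame,
    design: SurveyDesign,
    outcome_kind: str,
    model: int = 4,
    quartile_col: str = "quartile",
    min_events: int = 5,
) -> pd.DataFrame:
    """Refit the requested model within age bands (20-39, 40-59, >=60) and sex.

    Subgroup membership uses baseline age.  The stratifying variable is removed
    from the covariate set inside its own subgroups.  Empty subgroups (or
    subgroups with fewer than ``min_events`` events) are skipped with a log
    entry.
    """
    specs = [("age_band", name, (df["age"] >= lo) & (df["age"] < hi))
             for name, (lo, hi) in AGE_BANDS.items()]
    specs += [("sex", s, df["sex"] == s) for s in ("female", "male")]

    event_col = {"advanced_ckm": "advanced_ckm", "all_cause": "dead",
                 "cvd": "cvd_death", "premature": "dead"}[outcome_kind]
    out = []
    for kind, label, mask in specs:
        mask = mask.to_numpy()
        sub = df.loc[mask]
        if len(sub) == 0:
            logger.info("subgroup %s=%s empty; skipped", kind, label)
            continue
        if int(sub[event_col].astype(bool).sum()) < min_events:
            logger.info("subgroup %s=%s has < %d events; skipped", kind, label, min_events)
            continue
        covs = [c for c in MODEL_COVARIATES[model]
                if not (kind == "sex" and c == "sex")
                and not (kind == "age_band" and c == "age")]
        try:
            table = _one_fit(sub, design.subset(mask), outcome_kind, quartile_col, covs)
        except Exception as exc:  # noqa: BLE001 - subgroup fits may be unstable
            logger.warning("subgroup %s=%s fit failed: %s", kind, label, exc)
            continue
        table.insert(0, "subgroup", f"{kind}={label}")
        table.insert(1, "model", model)
        table.insert(2, "outcome", outcome_kind)
        out.append(table)
    if not out:
        return pd.DataFrame()
    return pd.concat(out, ignore_index=True)
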