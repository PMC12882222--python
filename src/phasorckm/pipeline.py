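"""End-to-end orchestration: preprocess -> phasor -> staging -> models -> tables.

A single configuration drives either a fully synthetic run (in-memory
actigraphy with known coupling, clinical profiles with known stages, survival
with known hazard effects) or a real-data layout (per-participant minute CSVs
plus cohort and mortality tables).  Exclusions follow the analytic flow --
age < 20, missing CKM data, missing anthropometrics, missing survival data,
missing device data -- and are logged step by step with exact conservation of
counts.  All outputs are plain CSV/JSON and are byte-identical across re-runs
with the same seed.
"""

from __future__ import annotations


import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .models import MODEL_COVARIATES, build_design, fit_sequential_models, stratified_fits
from .phasor import assign_quartiles, compute_phasor, phasor_table
from .preprocess import load_minute_records, segment_and_qc
from .simulate import (
    ActigraphySimSpec,
    CohortSimSpec,
    _draw_covariates,
    _survey_design,
    simulate_actigraphy,
    simulate_clinical,
)
from .splines import rcs_basis, spline_curve
from .staging import stage_dataframe
from .survey import SurveyDesign, SurveyLogit, weighted_descriptives
from .survival import SurveyCox, predicted_survival_curves, weighted_cox

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class SyntheticSpec:
    """Synthetic-mode knobs: cohort size, coupling spread, injected effects."""

    n_participants: int = 800
    n_days: int = 7
    rho_range: tuple = (0.05, 0.95)
    lag_sd_hours: float = 1.5
    missing_fraction_max: float = 0.25
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


@dataclass
class RealDataSpec:
    """Real-data layout: per-participant minute files plus cohort/mortality tables."""

    actigraphy_dir: str
    cohort_table: str
    mortality_table: str
    dialect: str = "csv-minute"


@dataclass
class PipelineConfig:
    """Full pipeline configuration (one of synthetic / real must be set)."""

    output_dir: str
    seed: int = 0
    synthetic: SyntheticSpec | None = None
    real: RealDataSpec | None = None
    min_valid_fraction: float = 0.8
    min_days: int = 4
    rcs_knots: int = 4
    outcomes: tuple = ("advanced_ckm", "all_cause", "cvd", "premature")
    run_stratified: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.synthetic is None) == (self.real is None):
            raise PipelineError("config: exactly one of synthetic / real must be provided")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synthetic", None)
        real = raw.pop("real", None)
        return cls(
            synthetic=SyntheticSpec(**syn) if syn is not None else None,
            real=RealDataSpec(**real) if real is not None else None,
            **raw,
        )


# ---------------------------------------------------------------------------
# Input acquisition
# ---------------------------------------------------------------------------

def _synthetic_inputs(cfg: PipelineConfig):
    """Generate recordings + cohort tables with known ground truth."""
    s = cfg.synthetic
    rng = np.random.default_rng(cfg.seed)
    n = s.n_participants

    rho = rng.uniform(*s.rho_range, n)
    lag = rng.normal(0.0, s.lag_sd_hours, n)
    lag = np.clip(lag, -11.9, 11.9)
    miss = rng.uniform(0.0, s.missing_fraction_max, n)
    child_seeds = rng.integers(0, 2**31 - 1, n)

    recordings = {}
    for i in range(n):
        pid = f"p{i:05d}"
        spec = ActigraphySimSpec(
            n_days=s.n_days, coupling_rho=float(rho[i]), lag_hours=float(lag[i]),
            missing_fraction=float(miss[i]), seed=int(child_seeds[i]),
        )
        rec = simulate_actigraphy(spec)
        rec.participant_id = pid
        recordings[pid] = rec

    cov = _draw_covariates(n, rng)
    cov.insert(0, "participant_id", [f"p{i:05d}" for i in range(n)])
    cohort_spec = CohortSimSpec(
        n=max(n, 4 * s.n_strata * s.psus_per_stratum),
        n_strata=s.n_strata, psus_per_stratum=s.psus_per_stratum,
        weight_range=s.weight_range,
    )
    design = _survey_design(n, cohort_spec, rng)
    cov = pd.concat([cov, design], axis=1)
    truth = {
        "beta_advanced": s.beta_advanced,
        "log_hr_allcause": s.log_hr_allcause,
        "log_hr_cvd": s.log_hr_cvd,
        "rho_range": list(s.rho_range),
    }
    return recordings, cov, rng, truth


def _synthetic_outcomes(cfg: PipelineConfig, table: pd.DataFrame, rng: np.random.Generator):
    """Draw CKM stage (via logistic on Q1) and survival with injected effects."""
    s = cfg.synthetic
    n = len(table)
    q1 = (table["quartile"].to_numpy() == 1).astype(float)

    logit = s.baseline_advanced_logit + s.beta_advanced * q1
    advanced = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))
    stage = np.where(
        advanced,
        rng.choice([3, 4], n, p=[0.5, 0.5]),
        rng.choice([1, 2], n, p=[0.4, 0.6]),
    )
    clinical = simulate_clinical(
        stage, seed=int(rng.integers(0, 2**31 - 1)),
        sex=table["sex"].to_numpy(), age=table["age"].to_numpy(),
    )
    clinical.insert(0, "participant_id", table["participant_id"].to_numpy())

    hazard = s.baseline_hazard * np.exp(s.log_hr_allcause * q1)
    t_death = rng.exponential(1.0 / hazard)
    t_cens = rng.exponential(1.0 / s.censor_rate, n)
    followup = np.minimum(np.minimum(t_death, t_cens), s.admin_censor_months)
    dead = t_death <= np.minimum(t_cens, s.admin_censor_months)
    p_cvd = np.where(
        q1 > 0,
        min(1.0, s.cvd_death_fraction * math.exp(s.log_hr_cvd - s.log_hr_allcause)),
        s.cvd_death_fraction,
    )
    cvd_death = dead & (rng.random(n) < p_cvd)
    mortality = pd.DataFrame({
        "participant_id": table["participant_id"].to_numpy(),
        "followup_months": followup,
        "dead": dead,
        "cvd_death": cvd_death,
    })
    return clinical, mortality


def _real_inputs(cfg: PipelineConfig):
    r = cfg.real
    adir = Path(r.actigraphy_dir)
    if not adir.is_dir():
        raise PipelineError(f"preprocess: actigraphy directory {adir} does not exist")
    recordings = {}
    suffix = "*.xpt" if r.dialect == "xpt-minute" else "*.csv"
    for f in sorted(adir.glob(suffix)):
        rec = load_minute_records(f, dialect=r.dialect)
        recordings[rec.participant_id] = rec
    if not recordings:
        raise PipelineError(f"preprocess: no {suffix} minute files found in {adir}")
    cohort = pd.read_csv(r.cohort_table)
    mortality = pd.read_csv(r.mortality_table)
    return recordings, cohort, mortality


# ---------------------------------------------------------------------------
# The run
# ---------------------------------------------------------------------------

def _write_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full pipeline; returns the manifest dict (also written to disk).

    Outputs (CSV unless noted): phasor table, staged cohort, exclusion log,
    forest tables for advanced-CKM ORs and all-cause/CVD/premature HRs across
    Models 1-4, spline curves, predicted survival curves, weighted
    descriptives, subgroup estimates, and ``manifest.json``.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, cfg.log_level, logging.INFO))

    exclusions = []

    def log_step(step: str, n_before: int, n_after: int) -> None:
        exclusions.append({"step": step, "n_before": n_before,
                           "excluded": n_before - n_after, "n_after": n_after})

    # --- stage 1: inputs -------------------------------------------------
    try:
        if cfg.synthetic is not None:
            recordings, cohort, rng, truth = _synthetic_inputs(cfg)
            mortality = None  # generated after quartiles (effects are quartile-linked)
        else:
            recordings, cohort, mortality = _real_inputs(cfg)
            truth = None
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"inputs: {exc}") from exc

    n0 = len(cohort)

    # --- stage 2: phasor -------------------------------------------------
    try:
        results = {}
        for pid in sorted(recordings):
            days = segment_and_qc(recordings[pid], cfg.min_valid_fraction, cfg.min_days)
            results[pid] = compute_phasor(days)
        ptab = phasor_table(results)
    except Exception as exc:
        raise PipelineError(f"phasor: {exc}") from exc

    # --- stage 3: exclusion flow ----------------------------------------
    cohort = cohort.copy()
    n_before = len(cohort)
    cohort = cohort[cohort["age"] >= 20]
    log_step("age_lt_20", n_before, len(cohort))

    merged = cohort.merge(ptab, on="participant_id", how="left")
    n_before = len(merged)
    merged = merged[merged["magnitude"].notna()]
    log_step("missing_device_data", n_before, len(merged))

    try:
        merged["quartile"], cuts = assign_quartiles(merged["magnitude"].to_numpy())
        merged["quartile"] = merged["quartile"].astype(int)
    except Exception as exc:
        raise PipelineError(f"quartiles: {exc}") from exc

    # --- stage 4: clinical + staging -------------------------------------
    try:
        if cfg.synthetic is not None:
            clinical, mortality = _synthetic_outcomes(cfg, merged, rng)
        else:
            clinical = cohort
        staged = stage_dataframe(clinical)
        keep = ["participant_id", "ckm_stage", "advanced_ckm", "ckm_criteria"] + [
            c for c in ("bmi", "waist_cm") if c in staged.columns
        ]
        merged = merged.merge(staged[keep], on="participant_id", how="left")
    except Exception as exc:
        raise PipelineError(f"staging: {exc}") from exc

    n_before = len(merged)
    merged = merged[merged["ckm_stage"].notna()]
    log_step("missing_ckm_data", n_before, len(merged))

    n_before = len(merged)
    if "bmi" in merged.columns:
        merged = merged[merged["bmi"].notna()]
    log_step("missing_anthropometrics", n_before, len(merged))

    merged = merged.merge(mortality, on="participant_id", how="left")
    n_before = len(merged)
    merged = merged[merged["followup_months"].notna() & merged["dead"].notna()]
    log_step("missing_survival_data", n_before, len(merged))

    merged["advanced_ckm"] = merged["advanced_ckm"].astype(bool)
    merged["dead"] = merged["dead"].astype(bool)
    merged["cvd_death"] = merged["cvd_death"].astype(bool)
    merged["age_at_exit"] = merged["age"] + merged["followup_months"] / 12.0
    merged = merged.reset_index(drop=True)

    # exclusions can empty a PSU; the remaining singleton stratum is then a
    # certainty unit (contributes no between-PSU variance) rather than an error
    design = SurveyDesign.from_frame(merged, strict=False)

    # --- stage 5: models -------------------------------------------------
    forest_tables = {}
    try:
        for outcome in cfg.outcomes:
            forest_tables[outcome] = fit_sequential_models(merged, design, outcome)
    except Exception as exc:
        raise PipelineError(f"models: {exc}") from exc

    # restricted cubic splines of magnitude (Model-4 covariates)
    spline_frames = []
    try:
        mag = merged["magnitude"].to_numpy()
        rcs_design, basis = rcs_basis(mag, n_knots=cfg.rcs_knots,
                                      weights=design.weight, name="magnitude")
        cov4 = build_design(merged, MODEL_COVARIATES[4])
        grid = np.linspace(np.quantile(mag, 0.02), np.quantile(mag, 0.98), 60)
        from .phasor import weighted_quantile
        ref = weighted_quantile(mag, 0.5, design.weight, interpolate=True)
        if "advanced_ckm" in cfg.outcomes:
            X = pd.concat([rcs_design, cov4.reset_index(drop=True)], axis=1)
            res = SurveyLogit().fit(merged["advanced_ckm"].astype(float).to_numpy(), X, design)
            sc = spline_curve(res.params, res.cov_params, basis, grid, ref, res.df_design)
            sc.insert(0, "outcome", "advanced_ckm")
            spline_frames.append(sc)
        if "all_cause" in cfg.outcomes:
            from .coxph import CoxConvergenceError

            frame = pd.concat([merged[["followup_months", "dead"]].reset_index(drop=True),
                               rcs_design, cov4.reset_index(drop=True)], axis=1)
            try:
                res = SurveyCox().fit(frame, "followup_months", "dead",
                                      rcs_design.columns.tolist() + cov4.columns.tolist(),
                                      design)
                sc = spline_curve(res.params, res.cov_params, basis, grid, ref, res.df_design)
                sc.insert(0, "outcome", "all_cause")
                spline_frames.append(sc)
            except CoxConvergenceError as exc:
                logger.warning("all-cause spline model not estimable: %s", exc)
    except Exception as exc:
        raise PipelineError(f"splines: {exc}") from exc

    # predicted survival curves from the quartile-only weighted Cox
    try:
        from .models import exposure_dummies
        exp = exposure_dummies(merged)
        frame = pd.concat([merged[["followup_months", "dead"]].reset_index(drop=True),
                           exp.reset_index(drop=True)], axis=1)
        cox_q, _ = weighted_cox(frame, "followup_months", "dead",
                                exp.columns.tolist(), [], design)
        surv_curves = (predicted_survival_curves(cox_q, merged, exp.columns.tolist())
                       if cox_q is not None else pd.DataFrame())
    except Exception as exc:
        raise PipelineError(f"survival_curves: {exc}") from exc

    strat_frames = []
    if cfg.run_stratified:
        try:
            for outcome in cfg.outcomes:
                sf = stratified_fits(merged, design, outcome)
                if len(sf):
                    strat_frames.append(sf)
        except Exception as exc:
            raise PipelineError(f"stratified: {exc}") from exc

    try:
        desc = weighted_descriptives(
            merged, design,
            continuous=["magnitude", "age"] + (["bmi"] if "bmi" in merged else []),
            categorical=["sex", "race", "hypertension", "diabetes", "advanced_ckm"],
            by="quartile",
        )
    except Exception as exc:
        raise PipelineError(f"descriptives: {exc}") from exc

    # --- stage 6: outputs ------------------------------------------------
    _write_csv(ptab, out / "phasor_table.csv")
    _write_csv(merged, out / "staged_cohort.csv")
    _write_csv(pd.DataFrame(exclusions), out / "exclusions.csv")
    for outcome, tab in forest_tables.items():
        _write_csv(tab, out / f"forest_{outcome}.csv")
    if spline_frames:
        _write_csv(pd.concat(spline_frames, ignore_index=True), out / "spline_curves.csv")
    _write_csv(surv_curves, out / "survival_curves.csv")
    if strat_frames:
        _write_csv(pd.concat(strat_frames, ignore_index=True), out / "stratified_estimates.csv")
    _write_csv(desc, out / "descriptives.csv")

    manifest = {
        "package_version": __version__,
        "seed": cfg.seed,
        "mode": "synthetic" if cfg.synthetic is not None else "real",
        "n_input": int(n0),
        "n_analyzed": int(len(merged)),
        "quartile_cuts": [float(c) for c in cuts],
        "exclusions": exclusions,
        "ground_truth": truth,
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
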