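"""Survey-weighted Cox regression and predicted survival curves.

Cause-specific hazards: for cardiovascular mortality, deaths from other causes
are treated as censoring.  Premature mortality is death before attained age
70: follow-up is administratively censored at the attained-age-70 boundary and
participants already 70 or older at baseline are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .coxph import CoxConvergenceError, CoxFit, fit_cox
from .survey import SurveyDesign, taylor_linearized_cov

__all__ = [
    "SurveyCox",
    "SurveyCoxResult",
    "weighted_cox",
    "premature_death_model",
    "predicted_survival_curves",
]


@dataclass
class SurveyCoxResult:
    """Fitted survey-weighted Cox model with design-based covariance."""

    params: pd.Series
    cov_params: pd.DataFrame
    df_design: int
    n_obs: int
    n_events: int
    fit: CoxFit
    design: SurveyDesign

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = scipy.stats.t.ppf(1 - alpha / 2, self.df_design)
        return pd.DataFrame({
            "lower": self.params - tcrit * self.bse,
            "upper": self.params + tcrit * self.bse,
        })

    def hazard_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        ci = self.conf_int(alpha)
        return pd.DataFrame({
            "HR": np.exp(self.params),
            "ci_lower": np.exp(ci["lower"]),
            "ci_upper": np.exp(ci["upper"]),
            "se_log": self.bse,
        })


class SurveyCox:
    """Weighted Cox PH regression with Taylor-linearized stratified-cluster variance.

    Point estimates maximize the weighted partial likelihood (Efron ties); the
    covariance wraps per-PSU totals of the weighted score residuals in the
    inverse-information bread.
    """

    def fit(
        self,
        df: pd.DataFrame,
        duration_col: str,
        event_col: str,
        covariate_cols: list,
        design: SurveyDesign,
    ) -> SurveyCoxResult:
        covariate_cols = list(covariate_cols)
        X = df[covariate_cols].astype(float).to_numpy()
        t = df[duration_col].to_numpy(dtype=float)
        e = df[event_col].to_numpy(dtype=bool)
        if np.any(t < 0):
            raise ValueError("follow-up times must be nonnegative")
        fit = fit_cox(t, e, X, weights=design.weight)
        cov = taylor_linearized_cov(fit.score_contribs, design, fit.naive_cov)
        return SurveyCoxResult(
            params=pd.Series(fit.beta, index=covariate_cols),
            cov_params=pd.DataFrame(cov, index=covariate_cols, columns=covariate_cols),
            df_design=design.degrees_of_freedom,
            n_obs=len(df),
            n_events=fit.n_events,
            fit=fit,
            design=design,
        )


def _estimable_exposure_cols(df, event_col, exposure_cols):
    """Exposure dummies whose level carries at least one event."""
    ok, dropped = [], []
    for c in exposure_cols:
        if df.loc[df[c].astype(bool), event_col].astype(bool).any():
            ok.append(c)
        else:
            dropped.append(c)
    return ok, dropped


def weighted_cox(
    df: pd.DataFrame,
    duration_col: str,
    event_col: str,
    exposure_cols: list,
    covariate_cols: list,
    design: SurveyDesign,
) -> tuple[SurveyCoxResult | None, pd.DataFrame]:
    """Fit time ~ exposure dummies + covariates; return (result, tidy HR table).

    An exposure level with no events is flagged non-estimable (NaN row) rather
    than sent into a divergent fit.
    """
    est_cols, dropped = _estimable_exposure_cols(df, event_col, exposure_cols)
    cols = est_cols + list(covariate_cols)
    try:
        res = SurveyCox().fit(df, duration_col, event_col, cols, design)
        table = res.hazard_ratios().reindex(list(exposure_cols))
    except CoxConvergenceError:
        res = None
        table = pd.DataFrame(
            np.nan, index=list(exposure_cols),
            columns=["HR", "ci_lower", "ci_upper", "se_log"],
        )
    table.insert(0, "term", table.index)
    table["n"] = len(df)
    table["events"] = int(df[event_col].astype(bool).sum())
    table["non_estimable"] = [c in dropped or res is None for c in exposure_cols]
    return res, table.reset_index(drop=True)


def premature_death_model(
    df: pd.DataFrame,
    exposure_cols: list,
    covariate_cols: list,
    design: SurveyDesign,
    age_col: str = "age",
    duration_col: str = "followup_months",
    dead_col: str = "dead",
    age_at_exit_col: str = "age_at_exit",
) -> tuple[SurveyCoxResult | None, pd.DataFrame]:
    """Cox model for premature mortality (death before attained age 70).

    Participants aged >= 70 at baseline are excluded; everyone else is
    administratively censored when they attain age 70, so a death at attained
    age >= 70 counts as censoring at the age-70 boundary.
    """
    keep = df[age_col].to_numpy(dtype=float) < 70.0
    sub = df.loc[keep].copy()
    subdes = design.subset(keep)
    months_to_70 = (70.0 - sub[age_col].to_numpy(dtype=float)) * 12.0
    fup = sub[duration_col].to_numpy(dtype=float)
    dead = sub[dead_col].to_numpy(dtype=bool)
    aae = sub[age_at_exit_col].to_numpy(dtype=float)
    sub["_premature_time"] = np.minimum(fup, months_to_70)
    sub["_premature_event"] = dead & (aae < 70.0)
    return weighted_cox(
        sub, "_premature_time", "_premature_event", exposure_cols, covariate_cols, subdes
    )


def predicted_survival_curves(
    result: SurveyCoxResult,
    df: pd.DataFrame,
    exposure_cols: list,
    times: np.ndarray | None = None,
    reference_label: str = "Q4",
) -> pd.DataFrame:
    """Predicted survival by exposure level, other covariates at weighted means.

    Uses the weighted Breslow (Efron-step) baseline cumulative hazard from the
    fit; curves are step functions evaluated on ``times`` (default: the event
    times, truncated at the last event).  Returns a tidy frame with columns
    ``months``, ``level``, ``survival``.
    """
    fit = result.fit
    if times is None:
        times = np.concatenate([[0.0], fit.baseline_times])
    times = np.asarray(times, dtype=float)
    times = times[times <= fit.baseline_times[-1]]  # no extrapolation beyond last event

    beta = result.params
    w = result.design.weight
    frames = []
    levels = list(exposure_cols) + [reference_label]
    for level in levels:
        # dummy pattern for this level; reference = all dummies zero
        eta = 0.0
        for c in exposure_cols:
            if c not in beta.index:
                continue  # non-estimable level already excluded from fit
            j = list(result.params.index).index(c)
            x_val = 1.0 if c == level else 0.0
            eta += beta[c] * (x_val - fit.x_center[j])
        surv = np.exp(-fit.cumhaz_at(times) * np.exp(eta))
        frames.append(pd.DataFrame({"months": times, "level": level, "survival": surv}))
    return pd.concat(frames, ignore_index=True)
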