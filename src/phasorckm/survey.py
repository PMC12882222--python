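"""Design-based inference for complex survey samples.

Point estimates are weighted maximum pseudo-likelihood estimates; variances
come from the Taylor-linearized (stratified cluster sandwich) estimator that
national health surveys recommend: per-PSU totals of the weighted score
contributions are centered within stratum, and

    meat = sum_h n_h/(n_h - 1) * sum_c (z_hc - zbar_h)(z_hc - zbar_h)'

is wrapped in the inverse-information bread.  Confidence intervals use
Student's t with the design degrees of freedom (number of PSUs minus number
of strata), matching R's ``survey`` conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm


class SingletonPSUError(ValueError):
    """A variance stratum contains fewer than two PSUs."""


@dataclass
class SurveyDesign:
    """Sampling weights plus the stratified-cluster variance structure."""

    weight: np.ndarray
    stratum: np.ndarray
    psu: np.ndarray
    #: strict designs reject singleton-PSU strata; subgroup designs relax this
    #: and treat singleton strata as certainty units (zero variance contribution)
    strict: bool = True

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.stratum = np.asarray(self.stratum)
        self.psu = np.asarray(self.psu)
        if np.any(self.weight <= 0):
            raise ValueError("weights must be positive")
        if not (len(self.weight) == len(self.stratum) == len(self.psu)):
            raise ValueError("design columns must have equal length")
        if self.strict:
            for h in np.unique(self.stratum):
                if len(np.unique(self.psu[self.stratum == h])) < 2:
                    raise SingletonPSUError(
                        f"stratum {h!r} has a single PSU; design-based variance is undefined"
                    )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, weight="weight", stratum="stratum", psu="psu",
                   strict: bool = True):
        return cls(df[weight].to_numpy(), df[stratum].to_numpy(), df[psu].to_numpy(),
                   strict=strict)

    def __len__(self) -> int:
        return len(self.weight)

    @property
    def degrees_of_freedom(self) -> int:
        """Design df: total PSUs minus number of strata."""
        n_psu = len(
            {(h, c) for h, c in zip(self.stratum.tolist(), self.psu.tolist())}
        )
        return n_psu - len(np.unique(self.stratum))

    def subset(self, mask: np.ndarray) -> "SurveyDesign":
        mask = np.asarray(mask, dtype=bool)
        return SurveyDesign(
            self.weight[mask], self.stratum[mask], self.psu[mask], strict=False
        )


def taylor_linearized_cov(
    score_contribs: np.ndarray, design: SurveyDesign, bread: np.ndarray
) -> np.ndarray:
    """Stratified-cluster sandwich covariance from per-observation weighted scores."""
    z = np.asarray(score_contribs, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    p = z.shape[1]
    meat = np.zeros((p, p))
    key = pd.MultiIndex.from_arrays([design.stratum, design.psu])
    totals = pd.DataFrame(z, index=key).groupby(level=[0, 1]).sum()
    for h, block in totals.groupby(level=0):
        zh = block.to_numpy()
        nh = zh.shape[0]
        if nh < 2:  # certainty unit: no between-PSU variance contribution
            continue
        centered = zh - zh.mean(axis=0)
        meat += nh / (nh - 1) * centered.T @ centered
    return bread @ meat @ bread


# ---------------------------------------------------------------------------
# Survey-weighted logistic regression
# ---------------------------------------------------------------------------

class SeparationWarningError(RuntimeError):
    """Perfect separation detected; the affected estimate has an infinite CI."""


@dataclass
class SurveyLogitResult:
    """Fitted survey-weighted logistic model."""

    params: pd.Series
    cov_params: pd.DataFrame
    df_design: int
    n_obs: int
    n_events: int
    separation: bool

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_params)), index=self.params.index)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        tcrit = scipy.stats.t.ppf(1 - alpha / 2, self.df_design)
        lo = self.params - tcrit * self.bse
        hi = self.params + tcrit * self.bse
        if self.separation:
            lo[:] = -np.inf
            hi[:] = np.inf
        return pd.DataFrame({"lower": lo, "upper": hi})

    def odds_ratios(self, alpha: float = 0.05) -> pd.DataFrame:
        """Per-coefficient OR with Wald (design-t) 95% CI and SE on the log scale."""
        ci = self.conf_int(alpha)
        return pd.DataFrame({
            "OR": np.exp(self.params),
            "ci_lower": np.exp(ci["lower"]),
            "ci_upper": np.exp(ci["upper"]),
            "se_log": self.bse,
        })


class SurveyLogit:
    """Survey-weighted logistic regression with Taylor-linearized variance.

    ``X`` must already contain any intercept/dummy columns.  Point estimates
    are the weighted pseudo-MLE (statsmodels GLM with frequency weights);
    the covariance is the stratified-cluster sandwich.
    """

    def __init__(self, add_intercept: bool = True):
        self.add_intercept = add_intercept

    def fit(self, y, X: pd.DataFrame, design: SurveyDesign) -> SurveyLogitResult:
        y = np.asarray(y, dtype=float)
        X = pd.DataFrame(X).astype(float)
        if self.add_intercept and "const" not in X.columns:
            X = sm.add_constant(X, has_constant="add")
        if len(y) != len(X) or len(y) != len(design):
            raise ValueError("y, X and design must align")

        glm = sm.GLM(y, X, family=sm.families.Binomial(), freq_weights=design.weight)
        try:
            fit = glm.fit(maxiter=200, tol=1e-10)
            converged = fit.converged
        except Exception:  # pragma: no cover - pathological inputs
            fit, converged = None, False

        separation = (not converged) or (fit is not None and np.any(np.abs(fit.params) > 15))
        if fit is None:
            raise SeparationWarningError("weighted logistic fit failed to converge")

        params = pd.Series(np.asarray(fit.params), index=X.columns)
        p_hat = np.asarray(fit.fittedvalues)
        Xv = X.to_numpy()
        w = design.weight
        info = Xv.T @ (Xv * (w * p_hat * (1 - p_hat))[:, None])
        bread = np.linalg.pinv(info)
        scores = Xv * (w * (y - p_hat))[:, None]
        cov = taylor_linearized_cov(scores, design, bread)
        return SurveyLogitResult(
            params=params,
            cov_params=pd.DataFrame(cov, index=X.columns, columns=X.columns),
            df_design=design.degrees_of_freedom,
            n_obs=len(y),
            n_events=int(y.sum()),
            separation=bool(separation),
        )


def weighted_logistic(
    df: pd.DataFrame,
    outcome: str,
    exposure_cols: list,
    covariate_cols: list,
    design: SurveyDesign,
) -> tuple[SurveyLogitResult, pd.DataFrame]:
    """Fit outcome ~ exposure dummies + covariates; return (result, tidy OR table)."""
    X = df[list(exposure_cols) + list(covariate_cols)]
    res = SurveyLogit().fit(df[outcome].to_numpy(), X, design)
    table = res.odds_ratios().loc[list(exposure_cols)]
    table.insert(0, "term", table.index)
    table["n"] = res.n_obs
    table["events"] = res.n_events
    return res, table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Weighted descriptive statistics
# ---------------------------------------------------------------------------

def _weighted_mean_se(y: np.ndarray, design: SurveyDesign) -> tuple[float, float]:
    w = design.weight
    total_w = w.sum()
    mean = float(np.sum(w * y) / total_w)
    # linearized residuals of the ratio estimator
    u = w * (y - mean) / total_w
    var = taylor_linearized_cov(u[:, None], design, np.eye(1))[0, 0]
    return mean, float(np.sqrt(var))


def weighted_descriptives(
    df: pd.DataFrame,
    design: SurveyDesign,
    continuous: list = (),
    categorical: list = (),
    by: str | None = None,
) -> pd.DataFrame:
    """Weighted means +/- SE, weighted medians, and weighted proportions.

    The estimated population total (sum of weights) is reported alongside, the
    mechanism behind survey-weighted population size estimates.  ``by`` splits
    the summaries by a grouping column (e.g. exposure quartile).
    """
    from .phasor import weighted_quantile

    def summarize(sub: pd.DataFrame, subdes: SurveyDesign, label) -> list[dict]:
        rows = [{"group": label, "variable": "_population", "statistic": "sum_of_weights",
                 "value": float(subdes.weight.sum())},
                {"group": label, "variable": "_n", "statistic": "count",
                 "value": float(len(sub))}]
        for c in continuous:
            y = sub[c].to_numpy(dtype=float)
            ok = np.isfinite(y)
            m, se = _weighted_mean_se(y[ok], subdes.subset(ok)) if ok.sum() else (np.nan, np.nan)
            med = weighted_quantile(y[ok], 0.5, subdes.weight[ok]) if ok.sum() else np.nan
            rows += [
                {"group": label, "variable": c, "statistic": "weighted_mean", "value": m},
                {"group": label, "variable": c, "statistic": "se", "value": se},
                {"group": label, "variable": c, "statistic": "weighted_median", "value": med},
            ]
        for c in categorical:
            levels = pd.unique(sub[c])
            wsum = subdes.weight.sum()
            for lev in sorted(levels, key=str):
                frac = float(subdes.weight[(sub[c] == lev).to_numpy()].sum() / wsum)
                rows.append({"group": label, "variable": f"{c}={lev}",
                             "statistic": "weighted_proportion", "value": frac})
        return rows

    if by is None:
        rows = summarize(df, design, "overall")
    else:
        rows = summarize(df, design, "overall")
        for lev in sorted(pd.unique(df[by]), key=str):
            mask = (df[by] == lev).to_numpy()
            rows += summarize(df[mask], design.subset(mask), f"{by}={lev}")
    return pd.DataFrame(rows)
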