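import math
import warnings

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter

from phasorckm import (
    CohortSimSpec,
    SurveyCox,
    SurveyDesign,
    predicted_survival_curves,
    premature_death_model,
    simulate_cohort,
    weighted_cox,
)
from phasorckm.coxph import CoxConvergenceError, fit_cox
from phasorckm.models import exposure_dummies

warnings.filterwarnings("ignore", message=".*weights are not integers.*")


def iid_design(n):
    return SurveyDesign(np.ones(n), np.zeros(n, int), np.arange(n))


def toy_survival(n=500, beta=0.7, seed=0, round_months=True):
    rng = np.random.default_rng(seed)
    x = rng.binomial(1, 0.3, n).astype(float)
    z = rng.normal(size=n)
    t = rng.exponential(1 / (0.02 * np.exp(beta * x + 0.3 * z)))
    if round_months:
        t = np.ceil(t)
    c = np.minimum(np.ceil(rng.exponential(60, n)), 120)
    return pd.DataFrame({
        "T": np.minimum(t, c), "E": (t <= c).astype(int), "x": x, "z": z,
    })


class TestCoxEngine:
    @pytest.mark.parametrize("ties", [True, False])
    def test_matches_phreg_to_machine_precision(self, ties):
        """Efron partial-likelihood optimum agrees with an independent implementation."""
        import statsmodels.api as sm

        df = toy_survival(round_months=ties)
        fit = fit_cox(df["T"], df["E"], df[["x", "z"]].to_numpy())
        res = sm.PHReg(
            df["T"].to_numpy(), df[["x", "z"]].to_numpy(),
            status=df["E"].to_numpy(), ties="efron",
        ).fit(method="newton", tol=1e-12, disp=0)
        np.testing.assert_allclose(fit.beta, res.params, atol=1e-8)
        np.testing.assert_allclose(
            np.sqrt(np.diag(fit.naive_cov)), res.bse, atol=1e-8
        )

    def test_matches_lifelines_at_its_precision(self):
        # lifelines stops on a log-likelihood plateau of ~1e-9, which limits
        # agreement to ~1e-5 on coefficients
        df = toy_survival()
        fit = fit_cox(df["T"], df["E"], df[["x", "z"]].to_numpy())
        cph = CoxPHFitter()
        cph.fit(df, "T", "E", fit_options={"precision": 1e-9})
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)

    def test_weighted_matches_lifelines(self):
        df = toy_survival()
        w = np.random.default_rng(5).uniform(0.5, 3.0, len(df))
        fit = fit_cox(df["T"], df["E"], df[["x", "z"]].to_numpy(), weights=w)
        cph = CoxPHFitter()
        cph.fit(df.assign(w=w), "T", "E", weights_col="w",
                fit_options={"precision": 1e-9})
        np.testing.assert_allclose(fit.beta, cph.params_.values, atol=1e-5)

    def test_score_residuals_sum_to_zero_at_mle(self):
        df = toy_survival()
        w = np.random.default_rng(5).uniform(0.5, 3.0, len(df))
        fit = fit_cox(df["T"], df["E"], df[["x", "z"]].to_numpy(), weights=w)
        assert np.abs(fit.score_contribs.sum(axis=0)).max() < 1e-6

    def test_rescaling_all_weights_leaves_estimates_unchanged(self):
        # sampling weights are only defined up to a constant for the point estimate
        df = toy_survival(n=300, seed=3)
        w = np.random.default_rng(2).uniform(0.5, 5.0, len(df))
        fit1 = fit_cox(df["T"], df["E"], df[["x", "z"]].to_numpy(), weights=w)
        fit2 = fit_cox(df["T"], df["E"], df[["x", "z"]].to_numpy(), weights=7.3 * w)
        np.testing.assert_allclose(fit1.beta, fit2.beta, atol=1e-8)

    def test_no_events_raises(self):
        with pytest.raises(CoxConvergenceError):
            fit_cox(np.arange(1.0, 11.0), np.zeros(10, bool), np.ones((10, 1)))

    def test_baseline_cumhaz_nondecreasing(self):
        df = toy_survival()
        fit = fit_cox(df["T"], df["E"], df[["x"]].to_numpy())
        assert np.all(np.diff(fit.baseline_cumhaz) >= 0)
        assert fit.cumhaz_at(0.0) == 0.0


class TestSurveyCox:
    def test_hr_recovery_within_ci(self, small_cohort):
        df = small_cohort.table
        design = SurveyDesign.from_frame(df)
        dfx = df.join(exposure_dummies(df))
        res, table = weighted_cox(dfx, "followup_months", "dead",
                                  ["Q1", "Q2", "Q3"], [], design)
        ci = res.conf_int().loc["Q1"]
        assert ci["lower"] <= small_cohort.truth["log_hr_allcause"] <= ci["upper"]
        assert not table["non_estimable"].any()

    def test_quartile_without_events_flagged(self):
        df = toy_survival(n=200, seed=9)
        df["Q1"] = 0.0
        df.loc[:20, "Q1"] = 1.0
        df.loc[df["Q1"] == 1.0, "E"] = 0  # no events in the flagged level
        _, table = weighted_cox(df, "T", "E", ["Q1"], ["z"], iid_design(len(df)))
        row = table.set_index("term").loc["Q1"]
        assert row["non_estimable"]
        assert np.isnan(row["HR"])

    def test_design_variance_reduces_to_robust_for_iid(self):
        df = toy_survival(n=400, seed=4)
        res = SurveyCox().fit(df, "T", "E", ["x", "z"], iid_design(len(df)))
        cph = CoxPHFitter()
        cph.fit(df, "T", "E", robust=True, fit_options={"precision": 1e-9})
        # lifelines robust sandwich has no n/(n-1) factor and uses Breslow-style
        # residuals; agreement is approximate but tight at n=400
        np.testing.assert_allclose(res.bse.values, cph.standard_errors_.values, rtol=0.05)


class TestPrematureDeath:
    def frame(self):
        return pd.DataFrame({
            "followup_months": [60.0, 60.0, 4.8, 30.0],
            "dead": [True, True, True, False],
            "cvd_death": [False] * 4,
            "age": [67.0, 68.0, 69.5, 50.0],
            "age_at_exit": [72.0, 73.0, 69.9, 52.5],
            "Q1": [1.0, 0.0, 1.0, 0.0],
        })

    def test_death_after_attained_70_is_censored_at_boundary(self):
        df = self.frame()
        _, table = premature_death_model(df, ["Q1"], [], iid_design(4))
        # participant 0 and 1 die at ages 72/73 -> censored; participant 2 dies at 69.9 -> event
        assert table["events"].iloc[0] == 1

    def test_baseline_age_70_plus_excluded(self):
        df = self.frame()
        df.loc[3, "age"] = 75.0
        _, table = premature_death_model(df, ["Q1"], [], iid_design(4))
        assert table["n"].iloc[0] == 3

    def test_injected_premature_effect_recovered(self):
        coh = simulate_cohort(CohortSimSpec(n=4000, seed=21))
        df = coh.table.join(exposure_dummies(coh.table))
        design = SurveyDesign.from_frame(df)
        res, _ = premature_death_model(df, ["Q1", "Q2", "Q3"], [], design)
        ci = res.conf_int().loc["Q1"]
        # premature deaths inherit the all-cause hazard effect in the generator
        assert ci["lower"] <= coh.truth["log_hr_allcause"] <= ci["upper"]


class TestPredictedSurvival:
    def fit_quartile_cox(self, n=3000, seed=13, log_hr=math.log(2.0)):
        coh = simulate_cohort(CohortSimSpec(n=n, seed=seed, log_hr_allcause=log_hr))
        df = coh.table.join(exposure_dummies(coh.table))
        design = SurveyDesign.from_frame(df)
        res, _ = weighted_cox(df, "followup_months", "dead", ["Q1", "Q2", "Q3"], [], design)
        return res, df

    def test_curves_start_at_one_and_are_nonincreasing(self):
        res, df = self.fit_quartile_cox()
        curves = predicted_survival_curves(res, df, ["Q1", "Q2", "Q3"])
        for _, sub in curves.groupby("level"):
            s = sub.sort_values("months")["survival"].to_numpy()
            assert s[0] == pytest.approx(1.0, abs=1e-9)
            assert np.all(np.diff(s) <= 1e-12)
            assert np.all((s >= 0) & (s <= 1))

    def test_proportional_hazards_ordering(self):
        res, df = self.fit_quartile_cox()
        curves = predicted_survival_curves(res, df, ["Q1", "Q2", "Q3"])
        wide = curves.pivot(index="months", columns="level", values="survival")
        assert np.all(wide["Q1"].to_numpy() <= wide["Q4"].to_numpy() + 1e-12)

    def test_null_effect_curves_nearly_coincide(self):
        gaps = []
        for seed in range(10):
            res, df = self.fit_quartile_cox(n=3000, seed=100 + seed, log_hr=0.0)
            curves = predicted_survival_curves(res, df, ["Q1", "Q2", "Q3"])
            wide = curves.pivot(index="months", columns="level", values="survival")
            gaps.append(float((wide.max(axis=1) - wide.min(axis=1)).max()))
        assert np.mean(np.array(gaps) < 0.05) >= 0.9

    def test_no_extrapolation_beyond_last_event(self):
        res, df = self.fit_quartile_cox()
        last_event = res.fit.baseline_times[-1]
        curves = predicted_survival_curves(res, df, ["Q1", "Q2", "Q3"],
                                           times=np.linspace(0, 200, 50))
        assert curves["months"].max() <= last_event
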