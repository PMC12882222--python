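import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phasorckm import (
    ClinicalProfile,
    ckm_stage,
    egfr_ckd_epi_2021,
    has_metabolic_syndrome,
    kdigo_a_stage,
    kdigo_g_stage,
    kdigo_risk,
    stage_dataframe,
)
from phasorckm.simulate import profile_for_stage
from phasorckm.staging import UnstageableError


class TestEGFR:
    def test_reference_evaluation_female(self):
        # direct transcription: 142 * (0.8/0.7)^-1.200 * 0.9938^50 * 1.012
        expected = 142.0 * (0.8 / 0.7) ** -1.2 * 0.9938**50 * 1.012
        assert egfr_ckd_epi_2021(0.8, 50, "female") == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(89.707, abs=0.001)

    def test_reference_evaluation_male_low_creatinine(self):
        # below the kappa knot the other branch applies: 142 * (0.6/0.9)^-0.302 * 0.9938^30
        expected = 142.0 * (0.6 / 0.9) ** -0.302 * 0.9938**30
        assert egfr_ckd_epi_2021(0.6, 30, "male") == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("sex, kappa", [("female", 0.7), ("male", 0.9)])
    def test_piecewise_continuity_at_knot(self, sex, kappa):
        lo = egfr_ckd_epi_2021(kappa - 1e-9, 45, sex)
        hi = egfr_ckd_epi_2021(kappa + 1e-9, 45, sex)
        assert lo == pytest.approx(hi, rel=1e-6)

    def test_monotone_decreasing_in_creatinine(self):
        scr = np.linspace(0.3, 5.0, 50)
        vals = [egfr_ckd_epi_2021(s, 60, "male") for s in scr]
        assert np.all(np.diff(vals) < 0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            egfr_ckd_epi_2021(0.0, 50, "male")
        with pytest.raises(ValueError):
            egfr_ckd_epi_2021(1.0, 10, "male")


class TestKDIGO:
    @pytest.mark.parametrize(
        "egfr, g", [(120, "G1"), (90, "G1"), (89.9, "G2"), (60, "G2"), (59.9, "G3a"),
                    (45, "G3a"), (44.9, "G3b"), (30, "G3b"), (29.9, "G4"), (15, "G4"),
                    (14.9, "G5"), (0, "G5")],
    )
    def test_g_boundaries(self, egfr, g):
        assert kdigo_g_stage(egfr) == g

    @pytest.mark.parametrize(
        "uacr, a", [(0, "A1"), (29.9, "A1"), (30, "A2"), (300, "A2"), (300.1, "A3")]
    )
    def test_a_boundaries_30_and_300_in_a2(self, uacr, a):
        assert kdigo_a_stage(uacr) == a

    def test_full_heat_map(self):
        expected = {
            ("G1", "A1"): "low", ("G1", "A2"): "moderate", ("G1", "A3"): "high",
            ("G2", "A1"): "low", ("G2", "A2"): "moderate", ("G2", "A3"): "high",
            ("G3a", "A1"): "moderate", ("G3a", "A2"): "high", ("G3a", "A3"): "very_high",
            ("G3b", "A1"): "high", ("G3b", "A2"): "very_high", ("G3b", "A3"): "very_high",
            ("G4", "A1"): "very_high", ("G4", "A2"): "very_high", ("G4", "A3"): "very_high",
            ("G5", "A1"): "very_high", ("G5", "A2"): "very_high", ("G5", "A3"): "very_high",
        }
        for (g, a), risk in expected.items():
            assert kdigo_risk(g, a) == risk


class TestMetabolicSyndrome:
    def base(self, **kw):
        d = dict(sex="male", age=50, waist_cm=90, bmi=24, fpg_mg_dl=90,
                 triglycerides_mg_dl=100, hdl_mg_dl=50, sbp=120, dbp=75)
        d.update(kw)
        return ClinicalProfile(**d)

    def test_three_components_true(self):
        p = self.base(waist_cm=110, triglycerides_mg_dl=200, hdl_mg_dl=35)
        assert has_metabolic_syndrome(p) is True

    def test_two_components_false(self):
        p = self.base(waist_cm=110, triglycerides_mg_dl=200)
        assert has_metabolic_syndrome(p) is False

    def test_borderline_values_inclusive(self):
        p = self.base(triglycerides_mg_dl=150, fpg_mg_dl=100, sbp=130, dbp=85)
        assert has_metabolic_syndrome(p) is True

    def test_undecidable_with_missing_components(self):
        p = self.base(waist_cm=110, triglycerides_mg_dl=None, hdl_mg_dl=None,
                      fpg_mg_dl=None)
        assert has_metabolic_syndrome(p) is None


class TestCKMStage:
    def test_worked_examples_span_all_stages(self):
        cases = [
            (dict(sex="female", age=45, waist_cm=80, bmi=23.0), 0),
            (dict(sex="male", age=45, waist_cm=95, bmi=27.0, fpg_mg_dl=110), 1),
            (dict(sex="male", age=45, waist_cm=95, bmi=23.0, triglycerides_mg_dl=140), 2),
            (dict(sex="male", age=45, waist_cm=95, bmi=23.0, scr_mg_dl=3.0, uacr_mg_g=20), 3),
            (dict(sex="female", age=60, waist_cm=80, bmi=23.0, cvd_history=True), 4),
        ]
        for kwargs, expected in cases:
            res = ckm_stage(ClinicalProfile(**kwargs))
            assert res.stage == expected
            assert res.advanced == (expected >= 3)

    def test_prediabetes_band_as_printed(self):
        base = dict(sex="male", age=40, waist_cm=90, bmi=23.0)
        assert ckm_stage(ClinicalProfile(**base, fpg_mg_dl=100)).stage == 1
        assert ckm_stage(ClinicalProfile(**base, fpg_mg_dl=124)).stage == 1
        assert ckm_stage(ClinicalProfile(**base, fpg_mg_dl=99)).stage == 0
        assert ckm_stage(ClinicalProfile(**base, hba1c_pct=5.7)).stage == 1
        assert ckm_stage(ClinicalProfile(**base, hba1c_pct=6.4)).stage == 1

    def test_antidiabetic_rx_switch(self):
        p = ClinicalProfile(sex="male", age=40, waist_cm=90, bmi=23.0,
                            on_antidiabetic_rx=True)
        assert ckm_stage(p).stage == 1  # as printed: therapy counts as prediabetes
        assert ckm_stage(p, rx_counts_as_prediabetes=False).stage == 0

    def test_moderate_risk_ckd_is_stage_2(self):
        # eGFR in G3a with A1 -> moderate KDIGO risk
        p = ClinicalProfile(sex="male", age=70, waist_cm=90, bmi=23.0,
                            scr_mg_dl=1.5, uacr_mg_g=5.0)
        res = ckm_stage(p)
        assert res.stage == 2
        assert "moderate_or_high_risk_ckd" in res.qualifying_criteria

    def test_elevated_cvd_risk_predicate_is_stage_3(self):
        p = ClinicalProfile(sex="male", age=60, waist_cm=90, bmi=23.0,
                            ten_year_cvd_risk_elevated=True)
        assert ckm_stage(p).stage == 3

    def test_missing_rule_inputs_do_not_fire(self):
        # TG missing, waist below threshold, BMI known low -> stage 0, not an error
        p = ClinicalProfile(sex="female", age=50, waist_cm=80, bmi=22.0)
        assert ckm_stage(p).stage == 0

    def test_totally_missing_profile_unstageable(self):
        with pytest.raises(UnstageableError):
            ckm_stage(ClinicalProfile(sex="male", age=50))

    @settings(max_examples=300, derandomize=True, deadline=None)
    @given(
        sex=st.sampled_from(["male", "female"]),
        age=st.floats(20, 85),
        waist=st.floats(60, 140),
        bmi=st.floats(16, 50),
        fpg=st.floats(60, 300),
        hba1c=st.floats(4, 12),
        tg=st.floats(40, 600),
        hdl=st.floats(15, 100),
        sbp=st.floats(90, 200),
        dbp=st.floats(50, 120),
        scr=st.floats(0.3, 6.0),
        uacr=st.floats(0, 2000),
        flags=st.tuples(*[st.booleans()] * 6),
    )
    def test_total_and_deterministic_on_complete_profiles(
        self, sex, age, waist, bmi, fpg, hba1c, tg, hdl, sbp, dbp, scr, uacr, flags
    ):
        """Every complete profile maps to exactly one stage in 0..4, without exceptions."""
        adm, ahm, htn, dm, cvd, risk = flags
        p = ClinicalProfile(
            sex=sex, age=age, waist_cm=waist, bmi=bmi, fpg_mg_dl=fpg, hba1c_pct=hba1c,
            on_antidiabetic_rx=adm, triglycerides_mg_dl=tg, hdl_mg_dl=hdl, sbp=sbp,
            dbp=dbp, on_antihypertensive_rx=ahm, hypertension=htn, diabetes=dm,
            scr_mg_dl=scr, uacr_mg_g=uacr, cvd_history=cvd,
            ten_year_cvd_risk_elevated=risk,
        )
        r1 = ckm_stage(p)
        r2 = ckm_stage(p)
        assert r1.stage in (0, 1, 2, 3, 4)
        assert r1.stage == r2.stage
        assert r1.advanced == (r1.stage in (3, 4))

    def test_monotone_dominance_random_profiles(self, rng):
        """Adding a risk factor never lowers the assigned stage (10,000 profiles)."""
        escalations = [
            ("cvd_history", lambda p: True),
            ("uacr_mg_g", lambda p: 500.0),
            ("scr_mg_dl", lambda p: 3.0),
            ("triglycerides_mg_dl", lambda p: 400.0),
            ("hypertension", lambda p: True),
            ("diabetes", lambda p: True),
            ("bmi", lambda p: max(p["bmi"], 30.0)),
            ("waist_cm", lambda p: 130.0),
            ("fpg_mg_dl", lambda p: 110.0),
            ("ten_year_cvd_risk_elevated", lambda p: True),
        ]
        for _ in range(10_000):
            stage0 = int(rng.integers(0, 5))
            p = profile_for_stage(stage0, rng)
            before = ckm_stage(ClinicalProfile(**p)).stage
            name, esc = escalations[int(rng.integers(0, len(escalations)))]
            q = dict(p)
            q[name] = esc(p)
            after = ckm_stage(ClinicalProfile(**q)).stage
            assert after >= before, (name, p, q)


class TestStageDataFrame:
    def test_round_trip_with_audit_columns(self):
        rows = [profile_for_stage(s, 100 + s) for s in (0, 1, 2, 3, 4)]
        df = pd.DataFrame(rows)
        staged = stage_dataframe(df)
        assert list(staged["ckm_stage"]) == [0.0, 1.0, 2.0, 3.0, 4.0]
        assert list(staged["advanced_ckm"]) == [False, False, False, True, True]
        assert staged.loc[4, "ckm_criteria"] == "cvd_history"

    def test_unstageable_row_is_nan_not_crash(self):
        df = pd.DataFrame([
            profile_for_stage(2, 7),
            {"sex": "male", "age": 50.0},
        ])
        staged = stage_dataframe(df)
        assert staged["ckm_stage"].isna().tolist() == [False, True]
        assert staged.loc[1, "ckm_criteria"] == "unstageable"
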