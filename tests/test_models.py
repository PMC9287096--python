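"""Risk-equation engine: term evaluation, risk transform, scoring, units."""

import math

import numpy as np
import pandas as pd
import pytest

import deprisk as d
from deprisk.models import Factor, ModelSpecError, SexModel, TermDefinition, RiskModelSpec

from .conftest import random_profile
from .oracles import assign_risk_literal, pce_risk_literal, score2_risk_literal


def _toy_spec(coefs, terms, s0=0.95, c=0.0):
    sm = SexModel(
        terms=tuple(terms),
        coefficients=dict(coefs),
        centering_constant=c,
        baseline_survival_10y=s0,
    )
    spec = RiskModelSpec(
        model_name="toy", endpoint_id="toy", sex_models={"female": sm, "male": sm}
    )
    spec.validate()
    return spec


def _profile(**kw):
    base = dict(
        age=60.0, sex="M", systolic_bp=140.0, total_chol=6.0, hdl_chol=1.4,
        smoker=False, cigarettes_per_day=0.0,
    )
    base.update(kw)
    return d.CovariateProfile(**base)


class TestLinearPredictor:
    def test_zero_coefficients_give_zero_lp(self):
        spec = _toy_spec(
            {"age": 0.0}, [TermDefinition("age", (Factor("age"),))]
        )
        assert d.linear_predictor(_profile(), spec) == 0.0

    def test_affine_term_hand_value(self):
        # beta=0.1 on (age - 60), age 70 -> lp = 1.0
        spec = _toy_spec(
            {"age": 0.1},
            [TermDefinition("age", (Factor("age", "affine", 1.0, -60.0),))],
        )
        assert d.linear_predictor(_profile(age=70.0), spec) == pytest.approx(1.0)

    def test_log_of_invalid_value_names_term(self):
        spec = _toy_spec(
            {"ln_tc": 1.0},
            [TermDefinition("ln_tc", (Factor("total_chol", "log"),))],
        )
        prof = _profile()
        prof.total_chol = 0.0
        with pytest.raises(ValueError, match="ln_tc"):
            d.linear_predictor(prof, spec)

    def test_missing_covariate_named(self):
        spec = _toy_spec(
            {"dep": 1.0},
            [TermDefinition("dep", (Factor("simd", "affine", 0.1, 0.0),))],
        )
        prof = _profile(simd=None)
        with pytest.raises(ValueError, match="dep"):
            d.linear_predictor(prof, spec)


class TestTenYearRisk:
    def test_lp_equal_centering_gives_one_minus_s0(self):
        spec = _toy_spec(
            {"age": 0.0}, [TermDefinition("age", (Factor("age"),))], s0=0.92, c=3.7
        )
        assert d.ten_year_risk(3.7, spec, "M") == pytest.approx(1 - 0.92, abs=1e-15)

    def test_closed_form_doubling(self):
        # S0=0.95, lp - c = ln 2 -> risk = 1 - 0.95^2 = 0.0975
        spec = _toy_spec(
            {"age": 0.0}, [TermDefinition("age", (Factor("age"),))], s0=0.95, c=0.0
        )
        assert d.ten_year_risk(math.log(2), spec, "F") == pytest.approx(0.0975)

    def test_lower_boundary(self):
        spec = _toy_spec(
            {"age": 0.0}, [TermDefinition("age", (Factor("age"),))], s0=0.95
        )
        assert d.ten_year_risk(-50.0, spec, "F") < 1e-15

    def test_monotone_in_lp(self):
        spec = _toy_spec(
            {"age": 0.0}, [TermDefinition("age", (Factor("age"),))], s0=0.9
        )
        lps = np.linspace(-3, 3, 50)
        risks = d.ten_year_risk(lps, spec, "F")
        assert np.all(np.diff(risks) > 0)

    def test_nonfinite_lp_rejected(self):
        spec = _toy_spec(
            {"age": 0.0}, [TermDefinition("age", (Factor("age"),))]
        )
        with pytest.raises(ValueError):
            d.ten_year_risk(np.nan, spec, "F")


class TestSpecValidation:
    def test_packaged_specs_load(self, assign_spec, score2_spec, pce_spec):
        assert assign_spec.endpoint_id == "assign_cvd"
        assert score2_spec.sex_models["female"].centering_constant == 0.0
        assert pce_spec.cholesterol_units == "mg/dL"

    def test_s0_outside_unit_interval_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            """
model_name: bad
endpoint: x
female:
  terms: [{name: age, factors: [{covariate: age}]}]
  coefficients: {age: 0.1}
  baseline_survival_10y: 1.2
male:
  terms: [{name: age, factors: [{covariate: age}]}]
  coefficients: {age: 0.1}
  baseline_survival_10y: 0.9
"""
        )
        with pytest.raises(ModelSpecError, match="baseline_survival_10y"):
            d.load_model_spec(bad)

    def test_missing_male_block_named(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            """
model_name: bad
endpoint: x
female:
  terms: [{name: age, factors: [{covariate: age}]}]
  coefficients: {age: 0.1}
  baseline_survival_10y: 0.9
"""
        )
        with pytest.raises(ModelSpecError, match="male"):
            d.load_model_spec(bad)

    def test_coefficient_term_mismatch_rejected(self, tmp_path):
        bad = tmp_path / "bad.yaml"
        bad.write_text(
            """
model_name: bad
endpoint: x
female:
  terms: [{name: age, factors: [{covariate: age}]}]
  coefficients: {age: 0.1, extra: 0.2}
  baseline_survival_10y: 0.9
male:
  terms: [{name: age, factors: [{covariate: age}]}]
  coefficients: {age: 0.1, extra: 0.2}
  baseline_survival_10y: 0.9
"""
        )
        with pytest.raises(ModelSpecError, match="bijection"):
            d.load_model_spec(bad)


class TestOracleEquivalence:
    """Engine output vs literal transcriptions of the packaged equations."""

    def test_assign(self, assign_spec):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = random_profile(rng)
            expected = assign_risk_literal(
                p.sex, p.age, p.total_chol, p.hdl_chol, p.systolic_bp,
                p.cigarettes_per_day, p.diabetes, p.family_history_cvd, p.simd,
            )
            assert d.predict_risk(p, assign_spec) == pytest.approx(
                expected, abs=1e-12
            )

    def test_score2(self, score2_spec):
        rng = np.random.default_rng(12)
        for _ in range(20):
            p = random_profile(rng)
            expected = score2_risk_literal(
                p.sex, p.age, p.smoker, p.systolic_bp, p.diabetes,
                p.total_chol, p.hdl_chol,
            )
            assert d.predict_risk(p, score2_spec) == pytest.approx(
                expected, abs=1e-12
            )

    def test_pce(self, pce_spec):
        rng = np.random.default_rng(13)
        for _ in range(20):
            p = d.convert_units(random_profile(rng), "mmol/L", "mg/dL")
            expected = pce_risk_literal(
                p.sex, p.age, p.total_chol, p.hdl_chol, p.systolic_bp,
                p.bp_treated, p.smoker, p.diabetes,
            )
            assert d.predict_risk(p, pce_spec) == pytest.approx(
                expected, abs=1e-12
            )

    @pytest.mark.parametrize("name", ["assign", "score2", "pce"])
    def test_positive_coefficient_monotonicity(self, name):
        """Raising a covariate with positive weight never lowers the risk."""
        spec = d.load_packaged_spec(name)
        units = spec.cholesterol_units
        rng = np.random.default_rng(5)
        sweeps = {
            "systolic_bp": np.linspace(100, 180, 9),
            "age": np.linspace(40, 69, 9),
        }
        for cov, grid in sweeps.items():
            for _ in range(5):
                base = random_profile(rng)
                if units == "mg/dL":
                    base = d.convert_units(base, "mmol/L", "mg/dL")
                risks = []
                for v in grid:
                    import dataclasses

                    prof = dataclasses.replace(base, **{cov: float(v)})
                    risks.append(d.predict_risk(prof, spec))
                assert np.all(np.diff(risks) > -1e-12), (name, cov)


class TestScoreCohort:
    def test_identical_rows_identical_risks(self, score2_spec):
        row = dict(
            sex="F", age=55.0, systolic_bp=130.0, total_chol=5.5, hdl_chol=1.5,
            smoker=True, cigarettes_per_day=10.0, diabetes=False,
            family_history_cvd=False, bp_treated=False, simd=15.0,
        )
        cohort = pd.DataFrame([row] * 3)
        res = d.score_cohort(cohort, score2_spec)
        assert res.n_scored == 3
        assert len(set(res.risk)) == 1

    def test_missing_simd_flags_only_that_row(self, assign_spec, default_cohort):
        cohort = default_cohort.cohort.head(200).copy()
        for col in ("simd", "total_chol", "hdl_chol", "systolic_bp"):
            cohort[col] = cohort[col].fillna(default_cohort.truth[col].head(200))
        cohort.loc[cohort.index[5], "simd"] = np.nan
        res = d.score_cohort(cohort, assign_spec)
        assert res.flagged[5]
        assert res.n_flagged == 1
        assert np.isnan(res.risk[5]) and np.isfinite(res.risk[6])

    def test_scoring_is_pure(self, score2_spec, default_cohort):
        cohort = default_cohort.cohort
        r1 = d.score_cohort(cohort, score2_spec)
        r2 = d.score_cohort(cohort, score2_spec)
        assert np.array_equal(r1.risk, r2.risk, equal_nan=True)

    def test_row_order_invariance(self, score2_spec, default_cohort):
        cohort = default_cohort.cohort.head(500)
        perm = np.random.default_rng(3).permutation(len(cohort))
        r1 = d.score_cohort(cohort, score2_spec).risk
        r2 = d.score_cohort(cohort.iloc[perm].reset_index(drop=True), score2_spec).risk
        assert np.allclose(r1[perm], r2, equal_nan=True)

    def test_empty_cohort_rejected(self, score2_spec):
        with pytest.raises(ValueError, match="empty"):
            d.score_cohort(pd.DataFrame(columns=["sex", "age"]), score2_spec)


class TestConvertUnits:
    def test_known_conversion(self):
        p = _profile(total_chol=6.0)
        out = d.convert_units(p, "mmol/L", "mg/dL")
        assert out.total_chol == pytest.approx(232.02)
        assert out.systolic_bp == p.systolic_bp

    def test_round_trip(self):
        p = _profile(total_chol=5.37, hdl_chol=1.23)
        back = d.convert_units(
            d.convert_units(p, "mmol/L", "mg/dL"), "mg/dL", "mmol/L"
        )
        assert back.total_chol == pytest.approx(p.total_chol, rel=1e-9)
        assert back.hdl_chol == pytest.approx(p.hdl_chol, rel=1e-9)

    def test_identity_and_unknown_system(self):
        p = _profile()
        assert d.convert_units(p, "mmol/L", "mmol/L") == p
        with pytest.raises(ValueError, match="unknown unit system"):
            d.convert_units(p, "mmol/L", "furlongs")


class TestProfileInvariants:
    def test_nonsmoker_with_cigarettes_rejected(self):
        p = _profile(smoker=False, cigarettes_per_day=5.0)
        with pytest.raises(ValueError, match="cigarettes"):
            p.validate()

    def test_hdl_above_total_rejected(self):
        p = _profile(total_chol=4.0, hdl_chol=4.5)
        with pytest.raises(ValueError, match="hdl"):
            p.validate()
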