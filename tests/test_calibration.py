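"""Recalibration, observed-vs-predicted, deciles, slope/intercept, refits."""

import math

import numpy as np
import pandas as pd
import pytest

import deprisk as d
from deprisk.calibration import cloglog, deprivation_term_name
from deprisk.models import Factor, RiskModelSpec, SexModel, TermDefinition
from deprisk.survival import SurvivalSample


def _flat_spec(s0=0.95, c=0.0):
    sm = SexModel(
        terms=(TermDefinition("age", (Factor("age"),)),),
        coefficients={"age": 0.0},
        centering_constant=c,
        baseline_survival_10y=s0,
    )
    return RiskModelSpec("flat", "x", {"female": sm, "male": sm})


def _sample_with_observed(o, n=1000, censor_at=12.0):
    """No-censoring-before-horizon sample with KM(10) exactly o."""
    k = int(round(o * n))
    times = np.concatenate([np.linspace(0.5, 9.5, k), np.full(n - k, censor_at)])
    status = np.concatenate([np.ones(k, int), np.zeros(n - k, int)])
    return SurvivalSample(times, status)


class TestRecalibrateS0:
    def test_equal_lps_closed_form(self):
        spec = _flat_spec(s0=0.95, c=1.3)
        sample = _sample_with_observed(0.08, n=1000)
        lps = np.full(1000, 1.3)  # lp == centering constant for everyone
        res = d.recalibrate_s0({"female": lps}, {"female": sample}, spec)
        assert res.updated_s0["female"] == pytest.approx(1 - 0.08, abs=1e-9)

    def test_quadratic_hand_example(self):
        # exponents {2, 1}, O = 0.14: S0^2 + S0 - 1.72 = 0
        spec = _flat_spec(s0=0.9, c=0.0)
        n = 1000
        lps = np.concatenate([np.full(n // 2, math.log(2)), np.zeros(n // 2)])
        sample = _sample_with_observed(0.14, n=n)
        res = d.recalibrate_s0({"male": lps}, {"male": sample}, spec)
        root = (-1 + math.sqrt(1 + 4 * 1.72)) / 2
        assert res.updated_s0["male"] == pytest.approx(root, abs=1e-9)

    def test_closure_on_simulated_cohort(self, clean_config):
        sim = d.simulate_cohort(clean_config.replace(n=4000, seed=6))
        spec = d.study_spec(clean_config, include_deprivation=True)
        c = sim.cohort
        scores = d.score_cohort(c, spec)
        lp_by, fu_by = {}, {}
        for code, key in (("F", "female"), ("M", "male")):
            m = (c["sex"] == code).to_numpy()
            lp_by[key] = scores.lp[m]
            fu_by[key] = SurvivalSample(
                c["time_years"].to_numpy()[m], c["status"].to_numpy()[m]
            )
        res = d.recalibrate_s0(lp_by, fu_by, spec)
        assert res.residual < 1e-8
        # and mean predicted equals KM observed per sex after re-scoring
        spec2 = spec.with_baseline_survival(res.updated_s0)
        scores2 = d.score_cohort(c, spec2)
        for code, key in (("F", "female"), ("M", "male")):
            m = (c["sex"] == code).to_numpy()
            o = d.km_risk_at(fu_by[key], 10.0).risk
            assert scores2.risk[m].mean() == pytest.approx(o, abs=1e-8)

    def test_no_events_fails(self):
        spec = _flat_spec()
        sample = SurvivalSample([5.0, 6.0], [0, 0])
        with pytest.raises(ValueError, match="events"):
            d.recalibrate_s0(
                {"female": np.zeros(2)}, {"female": sample}, spec
            )


class TestOPRatio:
    def test_null_identity(self):
        sample = _sample_with_observed(0.10, n=500)
        o = d.km_risk_at(sample, 10.0).risk
        res = d.op_ratio_test(np.full(500, o), sample)
        assert res.z == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)
        assert res.ratio == pytest.approx(1.0)

    def test_z_matches_binomial_closed_form(self):
        # no censoring before horizon -> Greenwood SE = binomial SE
        n, o = 1000, 0.06
        sample = _sample_with_observed(o, n=n)
        se = math.sqrt(o * (1 - o) / n)
        pred = np.full(n, o - 2 * se)  # exactly 2 SE below observed
        res = d.op_ratio_test(pred, sample)
        assert res.z == pytest.approx(2.0, abs=1e-9)
        assert res.p == pytest.approx(0.0455, abs=2e-4)

    def test_zero_predictions(self):
        sample = _sample_with_observed(0.05, n=400)
        res = d.op_ratio_test(np.zeros(400), sample)
        assert res.predicted == 0.0
        assert res.z > 0

    def test_zero_events_reports_undefined_ratio(self):
        sample = SurvivalSample(np.full(200, 12.0), np.zeros(200, int))
        res = d.op_ratio_test(np.full(200, 0.05), sample)
        assert res.ratio is None
        assert res.z < 0  # predicted above observed zero


class TestDeciles:
    def test_equal_split_and_ordering(self):
        rng = np.random.default_rng(1)
        pred = rng.uniform(0.01, 0.3, 100)
        fu = d.simulate_events_for_risks(pred, seed=2)
        table = d.decile_calibration(
            pred, SurvivalSample(fu["time"], fu["status"])
        )
        assert list(table["n"]) == [10] * 10
        assert table["mean_predicted"].is_monotonic_increasing

    def test_tied_risks_use_stable_order(self):
        pred = np.full(30, 0.1)
        fu = d.simulate_events_for_risks(pred, seed=3)
        table = d.decile_calibration(pred, SurvivalSample(fu["time"], fu["status"]))
        assert sorted(table["n"]) == [3] * 10
        assert table["mean_predicted"].nunique() == 1

    def test_too_few_participants(self):
        with pytest.raises(ValueError, match="bins"):
            d.decile_calibration(
                np.ones(5) * 0.1, SurvivalSample(np.ones(5), np.ones(5, int))
            )

    def test_calibrated_simulation_has_small_decile_gaps(self):
        rng = np.random.default_rng(8)
        pred = rng.beta(2, 20, 50_000)
        fu = d.simulate_events_for_risks(pred, seed=9)
        table = d.decile_calibration(pred, SurvivalSample(fu["time"], fu["status"]))
        gaps = (table["km_observed"] - table["mean_predicted"]).abs()
        assert gaps.max() < 0.01


class TestSlopeIntercept:
    def test_overprediction_gives_negative_intercept(self):
        rng = np.random.default_rng(5)
        pred = rng.uniform(0.02, 0.2, 2000)
        fu = d.simulate_events_for_risks(pred, seed=6)
        sample = SurvivalSample(fu["time"], fu["status"])
        inflated = np.clip(pred * 1.6, 0, 1)  # model says higher than truth
        si = d.calibration_slope_intercept(
            np.log(pred), inflated, sample
        )
        assert si["intercept"] < 0

    def test_halving_lp_scale_roughly_doubles_slope(self, clean_config):
        sim = d.simulate_cohort(clean_config.replace(n=50_000, seed=12))
        spec = d.study_spec(clean_config, include_deprivation=True)
        scores = d.score_cohort(sim.cohort, spec)
        fu = d.simulate_from_spec(sim.cohort, spec, seed=13)
        sample = SurvivalSample(fu["time"], fu["status"])
        s1 = d.calibration_slope_intercept(scores.lp, scores.risk, sample)["slope"]
        s2 = d.calibration_slope_intercept(2 * scores.lp, scores.risk, sample)["slope"]
        assert s2 == pytest.approx(s1 / 2, rel=0.10)

    def test_constant_lp_rejected(self):
        sample = _sample_with_observed(0.1, n=100)
        with pytest.raises(ValueError, match="constant"):
            d.calibration_slope_intercept(
                np.zeros(100), np.full(100, 0.1), sample
            )

    def test_cloglog_domain(self):
        with pytest.raises(ValueError):
            cloglog(0.0)


class TestStratifiedReport:
    def test_shape_and_conservation(self, default_cohort):
        cfg = default_cohort.config
        spec = d.study_spec(cfg, include_deprivation=True)
        c = default_cohort.cohort
        scores = d.score_cohort(c, spec)
        fu = pd.DataFrame({"time": c["time_years"], "status": c["status"]})
        report = d.stratified_report(c, scores, fu, recalibrated=False)
        assert set(report.strata) == {
            "all", "group1_most_deprived", "group2", "group3_least_deprived"
        }
        group_n = sum(
            report.strata[k].n
            for k in ("group1_most_deprived", "group2", "group3_least_deprived")
        )
        assert group_n + report.missing_simd_n == report.strata["all"].n
        events_sum = sum(
            report.strata[k].n_events
            for k in ("group1_most_deprived", "group2", "group3_least_deprived")
        )
        assert events_sum <= report.strata["all"].n_events
        assert report.strata["all"].deciles is not None
        assert report.strata["all"].c_statistic > 0.6

    def test_deterministic_output(self, default_cohort):
        cfg = default_cohort.config
        spec = d.study_spec(cfg, include_deprivation=False)
        c = default_cohort.cohort
        scores = d.score_cohort(c, spec)
        fu = pd.DataFrame({"time": c["time_years"], "status": c["status"]})
        r1 = d.stratified_report(c, scores, fu, recalibrated=False)
        r2 = d.stratified_report(c, scores, fu, recalibrated=False)
        import json

        assert json.dumps(r1.to_dict(), sort_keys=True) == json.dumps(
            r2.to_dict(), sort_keys=True
        )


class TestRefitWithDeprivation:
    def test_zero_effect_ci_covers_one(self, clean_config):
        cfg = clean_config.replace(n=8000, seed=21)
        cfg.true_log_hrs["deprivation"] = 0.0
        sim = d.simulate_cohort(cfg)
        spec = d.study_spec(cfg, include_deprivation=True)
        fu = pd.DataFrame(
            {"time": sim.cohort["time_years"], "status": sim.cohort["status"]}
        )
        fits = d.refit_with_deprivation(sim.cohort, spec, fu)
        term = deprivation_term_name(fits["male"])
        hr, lo, hi = fits["male"].hr_with_ci(term)
        assert lo < 1.0 < hi

    def test_spec_without_simd_gets_term_appended(self, clean_config):
        sim = d.simulate_cohort(clean_config.replace(n=6000, seed=22))
        spec = d.study_spec(clean_config, include_deprivation=False)
        fu = pd.DataFrame(
            {"time": sim.cohort["time_years"], "status": sim.cohort["status"]}
        )
        fits = d.refit_with_deprivation(sim.cohort, spec, fu)
        assert "simd_per10" in fits["female"].coef.index

    def test_constant_deprivation_column_fails(self, clean_config):
        sim = d.simulate_cohort(clean_config.replace(n=2000, seed=23))
        c = sim.cohort.copy()
        c["simd"] = 20.0
        spec = d.study_spec(clean_config, include_deprivation=False)
        fu = pd.DataFrame({"time": c["time_years"], "status": c["status"]})
        with pytest.raises(ValueError, match="constant"):
            d.refit_with_deprivation(c, spec, fu)
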