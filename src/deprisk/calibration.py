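"""Baseline-survival recalibration and deprivation-stratified validation.

Implements the external-validation battery for a scored cohort:

* **recalibration** — replace each sex's 10-year baseline survival S0 with
  the value that makes mean predicted risk equal the sex-specific
  Kaplan–Meier observed 10-year risk in the *whole* cohort (never within a
  deprivation stratum);
* **observed vs predicted** — KM observed risk O, mean predicted risk P,
  ratio P/O, and a Z test (O - P) / SE_Greenwood(O) treating P as fixed;
* **decile calibration curves** — KM observed risk with 95% CI per decile of
  predicted risk;
* **calibration intercept and slope** — slope is the coefficient of the
  linear predictor in a Cox model with lp as the sole covariate; intercept is
  cloglog(O) - cloglog(P) at the horizon, cloglog(x) = ln(-ln(1 - x));
* **discrimination** — Harrell's C;
* **sex-specific Cox refits** of each score's term structure with the
  deprivation score (SIMD/10) as an additional risk factor.

All of the above run for the whole cohort and within deprivation groups 1-3;
participants with missing SIMD form an explicitly reported "missing" stratum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq

from .deprivation import DeprivationConfig, simd_groups
from .models import RiskModelSpec, ScoreResult
from .survival import CoxFit, KMEstimate, SurvivalSample, concordance, fit_cox, km_risk_at

logger = logging.getLogger(__name__)


def cloglog(x: float) -> float:
    """ln(-ln(1 - x)) for a probability x in (0, 1)."""
    if not 0.0 < x < 1.0:
        raise ValueError(f"cloglog requires x in (0,1), got {x}")
    return float(np.log(-np.log1p(-x)))


# ---------------------------------------------------------------------------
# recalibration


@dataclass
class RecalibrationResult:
    original_s0: dict[str, float]
    updated_s0: dict[str, float]
    observed: dict[str, float]
    residual: float  # max over sexes of |mean predicted - observed|
    iterations: int

    def to_dict(self) -> dict:
        return {
            "original_s0": self.original_s0,
            "updated_s0": self.updated_s0,
            "observed_10y": self.observed,
            "residual": self.residual,
            "iterations": self.iterations,
        }


def recalibrate_s0(
    lp_by_sex: dict[str, np.ndarray],
    follow_up_by_sex: dict[str, SurvivalSample],
    spec: RiskModelSpec,
    horizon: float = 10.0,
) -> RecalibrationResult:
    """Solve, per sex, mean_i[1 - S0^exp(lp_i - c)] = O_sex for S0.

    O_sex is the sex-specific KM observed risk at the horizon in the whole
    cohort. Bracketed root-finding (Brent) on (1e-12, 1 - 1e-12); the mean
    risk is monotone decreasing in S0, so the root is unique.
    """
    updated: dict[str, float] = {}
    observed: dict[str, float] = {}
    iters = 0
    residual = 0.0
    for sex, lps in lp_by_sex.items():
        lps = np.asarray(lps, dtype=float)
        lps = lps[np.isfinite(lps)]
        if len(lps) == 0:
            raise ValueError(f"no finite linear predictors for sex {sex!r}")
        sample = follow_up_by_sex[sex]
        if sample.n_events == 0:
            raise ValueError(f"no events in sex stratum {sex!r}: cannot recalibrate")
        o = km_risk_at(sample, horizon).risk
        if not 0.0 < o < 1.0:
            raise ValueError(
                f"observed risk {o} for sex {sex!r} leaves the root unbracketed"
            )
        sm = spec.for_sex(sex)
        e = np.exp(lps - sm.centering_constant)

        def mean_risk_gap(s0: float) -> float:
            return float(np.mean(1.0 - s0**e) - o)

        s0_new, res = brentq(
            mean_risk_gap, 1e-12, 1.0 - 1e-12, xtol=1e-15, rtol=1e-15,
            full_output=True,
        )
        updated[sex] = float(s0_new)
        observed[sex] = float(o)
        iters = max(iters, res.iterations)
        residual = max(residual, abs(mean_risk_gap(s0_new)))
    if residual >= 1e-8:
        raise RuntimeError(f"recalibration residual {residual:g} exceeds 1e-8")
    original = {s: spec.sex_models[s].baseline_survival_10y for s in lp_by_sex}
    return RecalibrationResult(
        original_s0=original,
        updated_s0=updated,
        observed=observed,
        residual=residual,
        iterations=iters,
    )


# ---------------------------------------------------------------------------
# observed vs predicted


@dataclass
class OPResult:
    observed: float
    predicted: float
    ratio: float | None  # P / O; None when O == 0
    z: float
    p: float
    se_observed: float
    n: int
    n_events: int


def op_ratio_test(
    pred: np.ndarray,
    sample: SurvivalSample,
    horizon: float = 10.0,
) -> OPResult:
    """Observed-versus-predicted comparison at the horizon.

    O is the KM risk, P the mean predicted risk (treated as fixed), the
    reported ratio is P/O, and Z = (O - P) / SE_Greenwood(O) with a two-sided
    normal p-value. With zero events the Greenwood SE degenerates to 0; a
    rule-of-three fallback SE (upper bound 3/n over 1.96) is substituted so Z
    remains informative, and the ratio is reported as undefined.
    """
    pred = np.asarray(pred, dtype=float)
    if pred.shape != sample.times.shape:
        raise ValueError("pred length must match the follow-up sample")
    if np.any(~np.isfinite(pred)):
        raise ValueError("predicted risks must be finite (drop flagged rows first)")
    km = km_risk_at(sample, horizon)
    o, p_mean = km.risk, float(pred.mean())
    se = km.se
    if se == 0.0:
        se = (3.0 / sample.n) / 1.96  # rule-of-three fallback
    z = (o - p_mean) / se
    return OPResult(
        observed=o,
        predicted=p_mean,
        ratio=(p_mean / o) if o > 0 else None,
        z=float(z),
        p=float(2.0 * stats.norm.sf(abs(z))),
        se_observed=km.se,
        n=sample.n,
        n_events=sample.n_events,
    )


# ---------------------------------------------------------------------------
# decile calibration


def decile_calibration(
    pred: np.ndarray,
    sample: SurvivalSample,
    horizon: float = 10.0,
    n_bins: int = 10,
) -> pd.DataFrame:
    """KM observed risk (cloglog 95% CI) per decile of predicted risk.

    Participants are ranked by predicted risk with stable tie-breaking by
    input order and split into near-equal bins (sizes differ by at most 1).
    """
    pred = np.asarray(pred, dtype=float)
    if len(pred) < n_bins:
        raise ValueError(
            f"n={len(pred)} is below {n_bins} bins; configure coarser bins"
        )
    order = np.argsort(pred, kind="stable")
    rows = []
    for i, idx in enumerate(np.array_split(order, n_bins), start=1):
        sub = SurvivalSample(sample.times[idx], sample.status[idx])
        km = km_risk_at(sub, horizon, ci="cloglog")
        rows.append(
            {
                "decile": i,
                "n": len(idx),
                "mean_predicted": float(pred[idx].mean()),
                "km_observed": km.risk,
                "ci_low": km.ci_low,
                "ci_high": km.ci_high,
                "n_events": km.n_events,
            }
        )
    return pd.DataFrame(rows)


def calibration_slope_intercept(
    lps: np.ndarray,
    pred: np.ndarray,
    sample: SurvivalSample,
    horizon: float = 10.0,
) -> dict:
    """Calibration slope (Cox on lp) and intercept (cloglog difference).

    slope: coefficient of the linear predictor as the sole covariate of a Cox
    model — 1 under perfect calibration of relative risks. intercept:
    cloglog(O) - cloglog(mean P) at the horizon — 0 when overall risk level
    is correct, negative when the model overpredicts.
    """
    lps = np.asarray(lps, dtype=float)
    if np.nanstd(lps) == 0:
        raise ValueError("linear predictors are constant; slope is undefined")
    fit = fit_cox(
        SurvivalSample(sample.times, sample.status, pd.DataFrame({"lp": lps}))
    )
    o = km_risk_at(sample, horizon).risk
    p_mean = float(np.asarray(pred, dtype=float).mean())
    return {
        "slope": float(fit.coef["lp"]),
        "slope_se": float(fit.se["lp"]),
        "intercept": cloglog(o) - cloglog(p_mean),
        "slope_method": "cox_on_linear_predictor",
        "intercept_method": "cloglog_observed_minus_cloglog_mean_predicted",
    }


# ---------------------------------------------------------------------------
# stratified report


@dataclass
class StratumResult:
    name: str
    n: int
    n_events: int
    observed: float | None = None
    observed_ci: tuple[float, float] | None = None
    predicted: float | None = None
    ratio: float | None = None
    z: float | None = None
    p: float | None = None
    significant: bool | None = None
    c_statistic: float | None = None
    slope: float | None = None
    intercept: float | None = None
    deciles: pd.DataFrame | None = None
    warning: str | None = None

    def to_dict(self) -> dict:
        out = {
            "stratum": self.name,
            "n": self.n,
            "events": self.n_events,
            "observed": self.observed,
            "observed_ci_low": self.observed_ci[0] if self.observed_ci else None,
            "observed_ci_high": self.observed_ci[1] if self.observed_ci else None,
            "predicted": self.predicted,
            "ratio_pred_over_obs": self.ratio,
            "z": self.z,
            "p": self.p,
            "significant_at_0.05": self.significant,
            "c_statistic": self.c_statistic,
            "calibration_slope": self.slope,
            "calibration_intercept": self.intercept,
            "warning": self.warning,
        }
        return out


@dataclass
class CalibrationReport:
    model_name: str
    recalibrated: bool
    horizon: float
    strata: dict[str, StratumResult]
    missing_simd_n: int
    ties_method: str = "efron"
    ci_method_deciles: str = "cloglog"

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "recalibrated": self.recalibrated,
            "horizon_years": self.horizon,
            "ties_method": self.ties_method,
            "decile_ci_method": self.ci_method_deciles,
            "missing_simd_n": self.missing_simd_n,
            "strata": {k: v.to_dict() for k, v in self.strata.items()},
        }

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([s.to_dict() for s in self.strata.values()]).drop(
            columns=["warning"]
        )


STRATUM_LABELS = {1: "group1_most_deprived", 2: "group2", 3: "group3_least_deprived"}


def _evaluate_stratum(
    name: str,
    pred: np.ndarray,
    lps: np.ndarray,
    times: np.ndarray,
    status: np.ndarray,
    horizon: float,
    min_decile_n: int = 10,
) -> StratumResult:
    n = len(pred)
    n_events = int(status.sum())
    if n == 0:
        return StratumResult(name=name, n=0, n_events=0, warning="empty stratum")
    sample = SurvivalSample(times, status)
    if n_events == 0:
        logger.warning("stratum %s has zero events; reporting O=0", name)
        return StratumResult(
            name=name,
            n=n,
            n_events=0,
            observed=0.0,
            predicted=float(pred.mean()),
            warning="zero events in stratum",
        )
    km = km_risk_at(sample, horizon, ci="cloglog")
    op = op_ratio_test(pred, sample, horizon)
    res = StratumResult(
        name=name,
        n=n,
        n_events=n_events,
        observed=op.observed,
        observed_ci=(km.ci_low, km.ci_high),
        predicted=op.predicted,
        ratio=op.ratio,
        z=op.z,
        p=op.p,
        significant=bool(op.p < 0.05),
    )
    try:
        res.c_statistic = concordance(sample, pred)
    except ValueError as err:
        res.warning = f"concordance unavailable: {err}"
    if n >= min_decile_n:
        res.deciles = decile_calibration(pred, sample, horizon)
    if np.nanstd(lps) > 0 and n_events >= 2:
        try:
            si = calibration_slope_intercept(lps, pred, sample, horizon)
            res.slope = si["slope"]
            res.intercept = si["intercept"]
        except Exception as err:  # degenerate small strata
            res.warning = f"slope/intercept unavailable: {err}"
    return res


def stratified_report(
    cohort: pd.DataFrame,
    scores: ScoreResult,
    follow_up: pd.DataFrame,
    recalibrated: bool,
    horizon: float = 10.0,
    dep_config: DeprivationConfig | None = None,
) -> CalibrationReport:
    """Full calibration/discrimination report, whole-cohort and per group.

    ``follow_up`` must carry ``time`` and ``status`` aligned with ``cohort``.
    Rows flagged as unscorable are excluded (and counted); participants with
    missing SIMD are excluded from group strata but retained in the
    whole-cohort stratum.
    """
    dep_config = dep_config or DeprivationConfig()
    if len(follow_up) != len(cohort):
        raise ValueError("follow_up must align with the cohort")
    pred = np.asarray(scores.risk, dtype=float)
    lps = np.asarray(scores.lp, dtype=float)
    times = follow_up["time"].to_numpy(dtype=float)
    status = follow_up["status"].to_numpy(dtype=int)
    usable = ~scores.flagged
    groups = simd_groups(cohort["simd"]) if "simd" in cohort.columns else np.full(
        len(cohort), np.nan
    )
    strata: dict[str, StratumResult] = {}
    mask_all = usable
    strata["all"] = _evaluate_stratum(
        "all", pred[mask_all], lps[mask_all], times[mask_all], status[mask_all], horizon
    )
    for g in (1, 2, 3):
        m = usable & (groups == g)
        strata[STRATUM_LABELS[g]] = _evaluate_stratum(
            STRATUM_LABELS[g], pred[m], lps[m], times[m], status[m], horizon
        )
    missing_n = int((usable & np.isnan(groups)).sum())
    report = CalibrationReport(
        model_name=scores.model_name,
        recalibrated=recalibrated,
        horizon=horizon,
        strata=strata,
        missing_simd_n=missing_n,
    )
    group_n = sum(
        strata[STRATUM_LABELS[g]].n for g in (1, 2, 3)
    )
    if group_n + missing_n != strata["all"].n:
        raise AssertionError("stratum sizes do not sum to the cohort size")
    return report


# ---------------------------------------------------------------------------
# deprivation refit


def refit_with_deprivation(
    cohort: pd.DataFrame,
    spec: RiskModelSpec,
    follow_up: pd.DataFrame,
) -> dict[str, CoxFit]:
    """Sex-specific Cox refits of the score's term structure plus SIMD/10.

    The design matrix re-evaluates the spec's own terms on the cohort; when no
    term already uses the deprivation score, a ``simd_per10`` column is
    appended (the deprivation covariate convention of scores that carry one).
    Participants with missing SIMD or any missing term value are excluded
    (complete case). Returns {"female": CoxFit, "male": CoxFit}; the
    deprivation hazard ratio is read off the simd term.
    """
    from .models import _column_values

    out: dict[str, CoxFit] = {}
    sex_col = cohort["sex"].astype(str).to_numpy()
    simd = pd.to_numeric(cohort.get("simd"), errors="coerce").to_numpy(dtype=float)
    times = follow_up["time"].to_numpy(dtype=float)
    status = follow_up["status"].to_numpy(dtype=int)
    for sex_code, sex_key in (("F", "female"), ("M", "male")):
        sm = spec.sex_models[sex_key]
        mask = sex_col == sex_code
        sub = cohort[mask]
        values = {
            name: _column_values(sub, name) for name in spec.required_covariates | {"simd"}
        }
        cols = {}
        has_simd_term = False
        with np.errstate(invalid="ignore"):
            for term in sm.terms:
                cols[term.name] = np.asarray(term.evaluate(values), dtype=float)
                if "simd" in term.covariates:
                    has_simd_term = True
        if not has_simd_term:
            cols["simd_per10"] = simd[mask] / 10.0
        X = pd.DataFrame(cols)
        ok = np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
        X = X[ok]
        if X.shape[0] == 0:
            raise ValueError(f"no complete-case rows for sex {sex_code!r}")
        for col in list(X.columns):
            if X[col].nunique() <= 1:
                if "simd" in col:
                    raise ValueError(
                        f"term {col!r} is constant in the {sex_key} stratum"
                    )
                # e.g. a treatment-split term when nobody is treated
                logger.warning(
                    "refit (%s): dropping constant term %r", sex_key, col
                )
                X = X.drop(columns=[col])
        sample = SurvivalSample(
            times[mask][ok], status[mask][ok], covariates=X.reset_index(drop=True)
        )
        if sample.n_events < X.shape[1] + 1:
            raise ValueError(
                f"{sex_key}: {sample.n_events} events for {X.shape[1]} terms"
            )
        out[sex_key] = fit_cox(sample)
    return out


def deprivation_term_name(fit: CoxFit) -> str:
    """Name of the deprivation term in a refit (simd-based column)."""
    for name in fit.coef.index:
        if "simd" in name:
            return name
    raise KeyError("no deprivation term in this fit")
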