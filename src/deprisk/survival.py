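"""Censoring-aware survival primitives.

Thin, contract-checked wrappers over lifelines: Kaplan–Meier risk at a
horizon with Greenwood uncertainty, Cox proportional-hazards fitting with
Efron tie handling, and Harrell's concordance. All three consume a
:class:`SurvivalSample` so the calibration layer never touches fitting
libraries directly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from lifelines.utils import concordance_index, survival_table_from_events
from scipy import stats

logger = logging.getLogger(__name__)

Z95 = stats.norm.ppf(0.975)


@dataclass
class SurvivalSample:
    """Right-censored follow-up, optionally with a covariate matrix."""

    times: np.ndarray
    status: np.ndarray
    covariates: pd.DataFrame | None = None
    offset: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        if self.times.shape != self.status.shape:
            raise ValueError("times and status must have equal length")
        if len(self.times) == 0:
            raise ValueError("survival sample is empty")
        if np.any(self.times <= 0):
            raise ValueError("all follow-up times must be > 0")
        if not set(np.unique(self.status)) <= {0, 1}:
            raise ValueError("status must be 0/1")
        if self.covariates is not None and len(self.covariates) != len(self.times):
            raise ValueError("covariate matrix row count must match times")

    @property
    def n(self) -> int:
        return len(self.times)

    @property
    def n_events(self) -> int:
        return int(self.status.sum())


@dataclass
class KMEstimate:
    horizon: float
    risk: float
    se: float
    ci_low: float
    ci_high: float
    n: int
    n_events: int
    n_at_risk: int
    supported: bool  # horizon within observed follow-up
    ci_method: str = "plain"


def km_risk_at(
    sample: SurvivalSample, horizon: float, ci: str = "plain"
) -> KMEstimate:
    """Product-limit risk 1 - S(horizon) with Greenwood standard error.

    ``ci='cloglog'`` uses the log(-log S) transform, which keeps the interval
    inside [0, 1] (used for decile plots); ``'plain'`` is risk +/- 1.96*se.
    When the horizon exceeds the last observed time the last estimate is
    carried forward and ``supported`` is False.
    """
    if horizon <= 0:
        raise ValueError("horizon must be > 0")
    table = survival_table_from_events(sample.times, sample.status)
    tab = table[(table.index > 0) & (table.index <= horizon)]
    d = tab["observed"].to_numpy(dtype=float)
    n_risk = tab["at_risk"].to_numpy(dtype=float)
    has = d > 0
    d, n_risk = d[has], n_risk[has]
    surv = float(np.prod(1.0 - d / n_risk)) if len(d) else 1.0
    # Greenwood: Var(S) = S^2 * sum d / (n (n - d))
    with np.errstate(divide="ignore", invalid="ignore"):
        gw_terms = d / (n_risk * (n_risk - d))
    if np.any(~np.isfinite(gw_terms)):  # S has hit 0
        gw_sum = np.inf
    else:
        gw_sum = float(gw_terms.sum()) if len(d) else 0.0
    se = 0.0 if surv == 0.0 else float(surv * np.sqrt(gw_sum))
    risk = 1.0 - surv
    supported = bool(horizon <= sample.times.max())
    if not supported:
        logger.warning(
            "horizon %.3g exceeds last observed time %.3g; estimate carried forward",
            horizon,
            sample.times.max(),
        )
    if ci == "cloglog" and 0.0 < surv < 1.0 and np.isfinite(gw_sum) and gw_sum > 0:
        se_theta = np.sqrt(gw_sum) / abs(np.log(surv))
        s_lo = surv ** np.exp(Z95 * se_theta)
        s_hi = surv ** np.exp(-Z95 * se_theta)
        ci_low, ci_high = 1.0 - s_hi, 1.0 - s_lo
        method = "cloglog"
    else:
        ci_low = max(0.0, risk - Z95 * se)
        ci_high = min(1.0, risk + Z95 * se)
        method = "plain"
    return KMEstimate(
        horizon=float(horizon),
        risk=risk,
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n=sample.n,
        n_events=sample.n_events,
        n_at_risk=int((sample.times >= horizon).sum()),
        supported=supported,
        ci_method=method,
    )


class CoxFitError(RuntimeError):
    """Cox model failed to converge (possibly monotone likelihood)."""


@dataclass
class CoxFit:
    """Cox proportional-hazards fit (Efron ties, Newton iterations)."""

    coef: pd.Series
    se: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    log_likelihood: float
    n: int
    n_events: int
    converged: bool
    ties: str = "efron"

    @property
    def hazard_ratios(self) -> pd.Series:
        return np.exp(self.coef)

    def hr_with_ci(self, term: str) -> tuple[float, float, float]:
        return (
            float(np.exp(self.coef[term])),
            float(np.exp(self.ci_low[term])),
            float(np.exp(self.ci_high[term])),
        )


def fit_cox(
    sample: SurvivalSample,
    tol: float = 1e-9,
    max_iter: int = 100,
    strata: list[str] | None = None,
) -> CoxFit:
    """Maximise the Cox partial likelihood (Efron tie handling) via lifelines.

    SEs come from the inverse observed information. ``strata`` names columns
    of the covariate matrix that define separate baseline hazards instead of
    entering the linear predictor. Constant covariates and apparent perfect
    separation (monotone likelihood) raise :class:`CoxFitError` with advice.
    """
    if sample.covariates is None or sample.covariates.shape[1] == 0:
        raise ValueError("fit_cox requires a covariate matrix")
    if sample.offset is not None:
        raise NotImplementedError(
            "offset terms are not supported by this Cox backend"
        )
    strata = list(strata or [])
    X = sample.covariates
    value_cols = [c for c in X.columns if c not in strata]
    for col in value_cols:
        if X[col].nunique(dropna=False) <= 1:
            raise CoxFitError(
                f"covariate {col!r} is constant; drop the degenerate term"
            )
    if sample.n_events < len(value_cols):
        raise CoxFitError(
            f"{sample.n_events} events for {len(value_cols)} terms: fit is unidentified"
        )
    df = X.copy()
    df[value_cols] = df[value_cols].astype(float)
    df["_time"] = sample.times
    df["_status"] = sample.status
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="_time",
                event_col="_status",
                strata=strata or None,
                fit_options={"precision": tol, "max_steps": max_iter},
            )
    except ConvergenceError as err:
        raise CoxFitError(
            f"Cox fit failed to converge in {max_iter} iterations "
            f"(check for separation or collinearity): {err}"
        ) from err
    if (cph.params_.abs() > 20).any():
        worst = cph.params_.abs().idxmax()
        raise CoxFitError(
            f"monotone likelihood suspected (|coef| of {worst!r} exceeds 20): "
            f"check the data for perfect separation"
        )
    ci = cph.confidence_intervals_
    return CoxFit(
        coef=cph.params_.copy(),
        se=cph.standard_errors_.copy(),
        ci_low=ci.iloc[:, 0].rename(None).set_axis(cph.params_.index),
        ci_high=ci.iloc[:, 1].rename(None).set_axis(cph.params_.index),
        log_likelihood=float(cph.log_likelihood_),
        n=sample.n,
        n_events=sample.n_events,
        converged=True,
    )


def concordance(sample: SurvivalSample, risk_scores: Sequence[float]) -> float:
    """Harrell's C for predicted *risks* (higher risk should mean earlier event).

    Usable pairs are those where ordering is determined despite censoring;
    score ties count 1/2.
    """
    risk_scores = np.asarray(risk_scores, dtype=float)
    if risk_scores.shape != sample.times.shape:
        raise ValueError("risk_scores length must match the sample")
    if sample.n_events == 0:
        raise ValueError("no usable pairs: sample has no events")
    # concordance_index expects higher score ~ longer survival
    return float(concordance_index(sample.times, -risk_scores, sample.status))
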