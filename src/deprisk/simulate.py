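"""Synthetic cohorts with deprivation-graded risk factors and known truth.

The generator stands in for a restricted population cohort: ~15,000 adults,
60% female, median age near 51, with covariates drawn conditionally on the
SIMD quintile so that risk factors show the observed socioeconomic gradient
(e.g., current smoking ~30% in the most deprived group versus ~8.5% in the
least deprived, diabetes 4.0% versus 2.0%). Event times follow a Weibull
proportional-hazards model with configurable true log-hazard ratios —
including a deprivation effect of 0.15 per SIMD/10 by default — plus
administrative censoring (staggered entry, >10 years of follow-up), random
dropout, competing non-cardiovascular death, and missing-completely-at-random
covariate missingness (6% for SIMD).

Ground truth (true linear predictor, uncensored event time, generative
parameters) travels alongside the cohort so every downstream estimator can be
checked against the quantity it claims to estimate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .models import Factor, RiskModelSpec, SexModel, TermDefinition

SIMD_MIN, SIMD_MAX = 0.94, 89.89
QUINTILE_BOUNDS = {  # (low, high) of the SIMD score within each quintile
    1: (33.81, SIMD_MAX),
    2: (20.98, 33.81),
    3: (13.67, 20.98),
    4: (7.94, 13.67),
    5: (SIMD_MIN, 7.94),
}

# generative linear-predictor terms: coefficient (log HR) and centering value
DEFAULT_TRUE_LOG_HRS = {
    "age": 0.070,  # per year
    "smoker": 0.55,
    "diabetes": 0.70,
    "systolic_bp": 0.012,  # per mmHg
    "total_chol": 0.15,  # per mmol/L
    "hdl_chol": -0.40,  # per mmol/L
    "family_history_cvd": 0.25,
    "deprivation": 0.15,  # per SIMD/10
}
TERM_CENTERS = {
    "age": 51.0,
    "smoker": 0.0,
    "diabetes": 0.0,
    "systolic_bp": 124.0,
    "total_chol": 5.4,
    "hdl_chol": 1.45,
    "family_history_cvd": 0.0,
    "deprivation": 1.76,  # mean SIMD/10 under the default mixture
}

_FATAL_CVD_CODES = ["I21.9", "I25.1", "I63.9", "I50.0", "R96.0"]
_FATAL_CVD_W = [0.30, 0.25, 0.20, 0.15, 0.10]
_NONFATAL_CODES = [
    ("icd10_diagnosis", "I21.0"),
    ("icd10_diagnosis", "I21.4"),
    ("icd10_diagnosis", "I22.0"),
    ("icd10_diagnosis", "I20.9"),
    ("icd10_diagnosis", "I63.9"),
    ("icd10_diagnosis", "I61.0"),
    ("icd10_diagnosis", "G45.9"),
    ("opcs4_procedure", "K40.1"),
    ("opcs4_procedure", "K49.1"),
    ("opcs4_procedure", "L29.5"),
]
_NONFATAL_W = [0.17, 0.13, 0.05, 0.15, 0.17, 0.05, 0.08, 0.07, 0.10, 0.03]
_NONCVD_DEATH_CODES = ["C34.9", "C50.9", "J44.9", "A41.9"]


@dataclass
class SimulationConfig:
    """Full generative model for a synthetic validation cohort."""

    n: int = 15_000
    seed: int = 1
    proportion_female: float = 0.60
    age_mean: float = 51.0
    age_sd: float = 10.0
    age_range: tuple[float, float] = (30.0, 75.0)
    # SIMD mixture: quintile probabilities (most to least deprived), then a
    # within-quintile draw (right-skewed Beta(1,3) in the open-ended top
    # quintile, uniform elsewhere)
    quintile_probs: tuple[float, ...] = (0.1235, 0.185, 0.185, 0.185, 0.3215)
    smoking_prev_by_quintile: tuple[float, ...] = (0.301, 0.22, 0.18, 0.14, 0.085)
    cigarettes_mean: float = 11.0  # mean extra cigarettes/day among smokers
    diabetes_prev_by_quintile: tuple[float, ...] = (0.040, 0.032, 0.028, 0.024, 0.020)
    sbp_mean: float = 124.0
    sbp_sd: float = 14.0
    sbp_shift_by_quintile: tuple[float, ...] = (4.0, 2.0, 1.0, 0.0, -1.0)
    sbp_age_slope: float = 0.35  # mmHg per year of age
    tchol_mean: float = 5.4
    tchol_sd: float = 1.0
    tchol_age_slope: float = 0.01
    hdl_mean_female: float = 1.55
    hdl_mean_male: float = 1.30
    hdl_sd: float = 0.30
    family_history_prev_by_quintile: tuple[float, ...] = (0.45, 0.42, 0.40, 0.38, 0.35)
    bp_treated_prev: float = 0.0
    rheumatoid_arthritis_prev: float = 0.02
    true_log_hrs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TRUE_LOG_HRS)
    )
    weibull_shape: float = 1.3
    weibull_scale_female: float = 134.0
    weibull_scale_male: float = 96.0
    admin_censor_range: tuple[float, float] = (10.5, 15.5)
    dropout_hazard: float = 0.008  # per year
    noncvd_death_rate: float = 0.004  # per year at the reference age
    noncvd_death_age_loghr: float = 0.07
    fatal_event_fraction: float = 0.25
    missingness: dict[str, float] = field(
        default_factory=lambda: {
            "simd": 0.06,
            "total_chol": 0.01,
            "hdl_chol": 0.01,
            "systolic_bp": 0.01,
        }
    )

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0 <= self.proportion_female <= 1:
            raise ValueError("proportion_female must lie in [0, 1]")
        if self.weibull_shape <= 0:
            raise ValueError("weibull_shape must be > 0")
        if abs(sum(self.quintile_probs) - 1.0) > 1e-9:
            raise ValueError("quintile_probs must sum to 1")
        for name in (
            "smoking_prev_by_quintile",
            "diabetes_prev_by_quintile",
            "family_history_prev_by_quintile",
        ):
            vals = getattr(self, name)
            if len(vals) != 5 or not all(0 <= v <= 1 for v in vals):
                raise ValueError(f"{name} must be 5 prevalences in [0, 1]")
        for key, rate in self.missingness.items():
            if not 0 <= rate <= 1:
                raise ValueError(f"missingness[{key!r}] must lie in [0, 1]")
        lo, hi = self.admin_censor_range
        if not 0 < lo <= hi:
            raise ValueError("admin_censor_range must be 0 < low <= high")

    def replace(self, **changes) -> "SimulationConfig":
        return dataclasses.replace(self, **changes)


def default_config() -> SimulationConfig:
    """The shipped defaults (the study conditions every test assumes)."""
    return SimulationConfig()


@dataclass
class SyntheticCohort:
    """Cohort table plus events and the generative ground truth."""

    cohort: pd.DataFrame
    events: pd.DataFrame
    truth: pd.DataFrame
    config: SimulationConfig

    def event_fraction_by(self, horizon: float = 10.0) -> float:
        t = self.cohort["time_years"].to_numpy()
        s = self.cohort["status"].to_numpy()
        return float(((s == 1) & (t <= horizon)).mean())


def _true_linear_predictor(df: pd.DataFrame, log_hrs: dict[str, float]) -> np.ndarray:
    lp = np.zeros(len(df))
    for term, beta in log_hrs.items():
        if beta == 0:
            continue
        col = "simd" if term == "deprivation" else term
        x = df[col].to_numpy(dtype=float)
        if term == "deprivation":
            x = x / 10.0
        lp += beta * (x - TERM_CENTERS[term])
    return lp


def simulate_cohort(config: SimulationConfig | None = None) -> SyntheticCohort:
    """Draw a fully reproducible synthetic cohort from the generative model.

    Covariates are drawn hierarchically (SIMD quintile first, then
    quintile-conditional risk factors), event times by inverse transform from
    the Weibull proportional-hazards model, censoring applied (administrative
    entry-stagger, dropout, competing non-cardiovascular death), and
    missingness injected last, so the ground-truth table stays complete.
    """
    config = config or default_config()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n

    female = rng.random(n) < config.proportion_female
    quintile = rng.choice([1, 2, 3, 4, 5], size=n, p=config.quintile_probs)
    simd = np.empty(n)
    for q, (lo, hi) in QUINTILE_BOUNDS.items():
        m = quintile == q
        if q == 1:  # open-ended deprived tail: right-skewed
            simd[m] = lo + (hi - lo) * rng.beta(1.0, 3.0, size=m.sum())
        else:
            simd[m] = rng.uniform(lo, hi, size=m.sum())

    lo_a, hi_a = config.age_range
    a = (lo_a - config.age_mean) / config.age_sd
    b = (hi_a - config.age_mean) / config.age_sd
    age = stats.truncnorm.rvs(
        a, b, loc=config.age_mean, scale=config.age_sd, size=n, random_state=rng
    )

    qidx = quintile - 1
    smoker = rng.random(n) < np.asarray(config.smoking_prev_by_quintile)[qidx]
    cigs = np.where(smoker, 1 + rng.poisson(config.cigarettes_mean, size=n), 0)
    diabetes = rng.random(n) < np.asarray(config.diabetes_prev_by_quintile)[qidx]
    sbp = (
        config.sbp_mean
        + np.asarray(config.sbp_shift_by_quintile)[qidx]
        + config.sbp_age_slope * (age - config.age_mean)
        + rng.normal(0.0, config.sbp_sd, size=n)
    )
    sbp = np.clip(sbp, 80.0, None)
    tchol = np.clip(
        config.tchol_mean
        + config.tchol_age_slope * (age - config.age_mean)
        + rng.normal(0.0, config.tchol_sd, size=n),
        2.5,
        None,
    )
    hdl_mean = np.where(female, config.hdl_mean_female, config.hdl_mean_male)
    hdl = np.clip(rng.normal(hdl_mean, config.hdl_sd), 0.5, tchol - 0.5)
    fh = rng.random(n) < np.asarray(config.family_history_prev_by_quintile)[qidx]
    bp_treated = rng.random(n) < config.bp_treated_prev
    ra = rng.random(n) < config.rheumatoid_arthritis_prev

    complete = pd.DataFrame(
        {
            "age": age,
            "simd": simd,
            "smoker": smoker,
            "cigarettes_per_day": cigs.astype(float),
            "diabetes": diabetes,
            "systolic_bp": sbp,
            "total_chol": tchol,
            "hdl_chol": hdl,
            "family_history_cvd": fh,
            "bp_treated": bp_treated,
        }
    )
    true_lp = _true_linear_predictor(complete, config.true_log_hrs)

    # Weibull PH: H0(t) = (t / scale)^shape, T = scale * (E / exp(lp))^(1/shape)
    scale = np.where(female, config.weibull_scale_female, config.weibull_scale_male)
    e = rng.exponential(size=n)
    t_event = scale * (e / np.exp(true_lp)) ** (1.0 / config.weibull_shape)

    admin = rng.uniform(*config.admin_censor_range, size=n)
    if config.dropout_hazard > 0:
        dropout = rng.exponential(1.0 / config.dropout_hazard, size=n)
    else:
        dropout = np.full(n, np.inf)
    death_rate = config.noncvd_death_rate * np.exp(
        config.noncvd_death_age_loghr * (age - config.age_mean)
    )
    t_death = rng.exponential(1.0 / death_rate, size=n)

    t_cens = np.minimum(np.minimum(admin, dropout), t_death)
    status = (t_event <= t_cens).astype(int)
    time = np.minimum(t_event, t_cens)
    time = np.maximum(time, 1e-6)

    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)])
    cohort = pd.DataFrame(
        {
            "id": ids,
            "sex": np.where(female, "F", "M"),
            **{c: complete[c].to_numpy() for c in complete.columns},
            "rheumatoid_arthritis": ra,
            "admin_censor_years": np.minimum(admin, dropout),
            "time_years": time,
            "status": status,
        }
    )

    events = _draw_event_records(
        rng, ids, time, status, t_death, t_cens, config
    )

    # MCAR missingness, injected after outcomes so truth stays complete
    for col, rate in config.missingness.items():
        if rate > 0 and col in cohort.columns:
            miss = rng.random(n) < rate
            cohort.loc[miss, col] = np.nan

    truth = complete.copy()
    truth.insert(0, "id", ids)
    truth["quintile"] = quintile
    truth["true_lp"] = true_lp
    truth["true_event_time"] = t_event
    truth["noncvd_death_time"] = t_death
    return SyntheticCohort(cohort=cohort, events=events, truth=truth, config=config)


def _draw_event_records(rng, ids, time, status, t_death, t_cens, config):
    """Coded event records consistent with the realised follow-up."""
    rows = []
    had_event = status == 1
    fatal = had_event & (rng.random(len(ids)) < config.fatal_event_fraction)
    nonfatal_idx = rng.choice(len(_NONFATAL_CODES), size=len(ids), p=_NONFATAL_W)
    fatal_codes = rng.choice(_FATAL_CVD_CODES, size=len(ids), p=_FATAL_CVD_W)
    for i in np.flatnonzero(had_event):
        if fatal[i]:
            rows.append((ids[i], time[i], "icd10_cause_of_death", fatal_codes[i], True))
        else:
            system, code = _NONFATAL_CODES[nonfatal_idx[i]]
            rows.append((ids[i], time[i], system, code, False))
    # competing non-CVD deaths observed within follow-up
    died = (~had_event) & (t_death <= t_cens + 1e-12)
    death_codes = rng.choice(_NONCVD_DEATH_CODES, size=len(ids))
    for i in np.flatnonzero(died):
        rows.append(
            (ids[i], t_death[i], "icd10_cause_of_death", death_codes[i], True)
        )
    # background non-qualifying admissions (hypertension) as noise
    n_noise = int(0.03 * len(ids))
    noise_who = rng.choice(len(ids), size=n_noise, replace=False)
    noise_t = rng.uniform(0.1, 10.0, size=n_noise)
    for i, t in zip(noise_who, noise_t):
        rows.append((ids[i], t, "icd10_diagnosis", "I10", False))
    ev = pd.DataFrame(
        rows, columns=["participant_id", "time_years", "code_system", "code", "fatal"]
    )
    return ev.sort_values(["participant_id", "time_years"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# auxiliary generators used by calibration checks


def simulate_events_for_risks(
    pred_risks: np.ndarray, horizon: float = 10.0, seed: int = 0
) -> pd.DataFrame:
    """Perfect-calibration outcomes: each participant's event probability by
    the horizon equals their predicted risk (Bernoulli event, uniform event
    time, censoring at the horizon otherwise)."""
    pred_risks = np.asarray(pred_risks, dtype=float)
    if np.any((pred_risks < 0) | (pred_risks > 1)):
        raise ValueError("risks must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    event = rng.random(len(pred_risks)) < pred_risks
    t = np.where(event, rng.uniform(0.0, horizon, size=len(pred_risks)), horizon)
    t = np.maximum(t, 1e-9)
    return pd.DataFrame({"time": t, "status": event.astype(int)})


def simulate_from_spec(
    cohort: pd.DataFrame,
    spec: RiskModelSpec,
    seed: int = 0,
    shape: float = 1.3,
    admin_censor_range: tuple[float, float] = (10.5, 15.5),
) -> pd.DataFrame:
    """Outcomes drawn so the *spec itself* is the true model.

    The cumulative baseline hazard is Weibull-shaped and anchored to the
    spec's S0(10): H0(t) = -ln(S0_sex) * (t/10)^shape, so P(T <= 10 | lp)
    equals the spec's predicted 10-year risk exactly and the Cox calibration
    slope of lp is 1 in truth. Censoring is administrative only, beyond the
    10-year horizon.
    """
    from .models import score_cohort

    scores = score_cohort(cohort, spec)
    if scores.flagged.any():
        raise ValueError(
            "cohort has unscorable rows; simulate_from_spec needs complete covariates"
        )
    rng = np.random.default_rng(seed)
    sex = cohort["sex"].astype(str).to_numpy()
    lam0 = np.empty(len(cohort))
    expo = np.empty(len(cohort))
    for code, key in (("F", "female"), ("M", "male")):
        sm = spec.sex_models[key]
        m = sex == code
        lam0[m] = -np.log(sm.baseline_survival_10y)
        expo[m] = np.exp(scores.lp[m] - sm.centering_constant)
    e = rng.exponential(size=len(cohort))
    t_event = 10.0 * (e / (lam0 * expo)) ** (1.0 / shape)
    admin = rng.uniform(*admin_censor_range, size=len(cohort))
    status = (t_event <= admin).astype(int)
    time = np.maximum(np.minimum(t_event, admin), 1e-9)
    return pd.DataFrame({"time": time, "status": status}, index=cohort.index)


# ---------------------------------------------------------------------------
# study specs: the generative truth expressed as a risk-model spec


def study_spec(
    config: SimulationConfig | None = None,
    include_deprivation: bool = True,
    model_name: str | None = None,
) -> RiskModelSpec:
    """Risk-model spec whose terms mirror the generative model.

    With ``include_deprivation=True`` the spec carries the SIMD/10 term and is
    perfectly specified (the deprivation-aware, ASSIGN-style case); with
    ``False`` the deprivation effect is omitted from the score while still
    present in the outcomes (the deprivation-blind, SCORE2/PCE-style case).
    Baseline survival is the generative S0(10) per sex.
    """
    config = config or default_config()
    terms = [
        TermDefinition("age", (Factor("age", "affine", 1.0, -TERM_CENTERS["age"]),)),
        TermDefinition("smoker", (Factor("smoker", "indicator"),)),
        TermDefinition("diabetes", (Factor("diabetes", "indicator"),)),
        TermDefinition(
            "systolic_bp",
            (Factor("systolic_bp", "affine", 1.0, -TERM_CENTERS["systolic_bp"]),),
        ),
        TermDefinition(
            "total_chol",
            (Factor("total_chol", "affine", 1.0, -TERM_CENTERS["total_chol"]),),
        ),
        TermDefinition(
            "hdl_chol", (Factor("hdl_chol", "affine", 1.0, -TERM_CENTERS["hdl_chol"]),)
        ),
        TermDefinition(
            "family_history_cvd", (Factor("family_history_cvd", "indicator"),)
        ),
    ]
    coefs = {
        name: config.true_log_hrs[name]
        for name in (
            "age",
            "smoker",
            "diabetes",
            "systolic_bp",
            "total_chol",
            "hdl_chol",
            "family_history_cvd",
        )
    }
    if include_deprivation:
        terms.append(
            TermDefinition(
                "simd_per10",
                (Factor("simd", "affine", 0.1, -TERM_CENTERS["deprivation"]),),
            )
        )
        coefs["simd_per10"] = config.true_log_hrs["deprivation"]
    sex_models = {}
    for key, scale in (
        ("female", config.weibull_scale_female),
        ("male", config.weibull_scale_male),
    ):
        s0 = float(np.exp(-((10.0 / scale) ** config.weibull_shape)))
        sex_models[key] = SexModel(
            terms=tuple(terms),
            coefficients=dict(coefs),
            centering_constant=0.0,
            baseline_survival_10y=s0,
        )
    name = model_name or (
        "study_deprivation_aware" if include_deprivation else "study_deprivation_blind"
    )
    spec = RiskModelSpec(
        model_name=name,
        endpoint_id="cvd_composite",
        sex_models=sex_models,
    )
    spec.validate()
    return spec
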