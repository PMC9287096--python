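"""Generic engine for survival-type cardiovascular risk equations.

A risk model of the ASSIGN/SCORE2/PCE family predicts 10-year event risk as

    risk = 1 - S0(10) ** exp(lp - c)

where ``lp`` is a sex-specific linear predictor over transformed covariates,
``c`` a centering constant (the linear predictor of the derivation cohort's
reference profile, 0 for pre-centered equations such as SCORE2) and ``S0(10)``
the 10-year baseline survival. Equations are expressed as *data*: each term is
a product of factors, each factor a transform (identity, affine, natural log,
indicator) of one raw covariate. That representation covers ASSIGN's linear
terms, SCORE2's centered terms and age interactions, and PCE's log terms,
squared log-age and treatment-split blood-pressure terms without any
model-specific code.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

CHOL_MMOL_TO_MGDL = 38.67

SEXES = ("female", "male")

#: raw covariates a term factor may reference
COVARIATE_NAMES = frozenset(
    {
        "age",
        "systolic_bp",
        "total_chol",
        "hdl_chol",
        "cigarettes_per_day",
        "simd",
        "smoker",
        "diabetes",
        "family_history_cvd",
        "bp_treated",
        "rheumatoid_arthritis",
    }
)


class ModelSpecError(ValueError):
    """Raised when a risk-model specification violates its schema."""


@dataclass
class CovariateProfile:
    """One participant's raw covariates, in the unit system of the caller.

    Cholesterol fields are mmol/L unless converted with :func:`convert_units`.
    ``simd`` is the Scottish Index of Multiple Deprivation score (0.94-89.89
    in the 2009 revision; higher = more deprived) and may be ``None``.
    """

    age: float
    sex: str  # "F" or "M"
    systolic_bp: float
    total_chol: float
    hdl_chol: float
    smoker: bool
    cigarettes_per_day: float = 0.0
    diabetes: bool = False
    family_history_cvd: bool = False
    bp_treated: bool = False
    rheumatoid_arthritis: bool = False
    simd: float | None = None

    def validate(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"sex must be 'F' or 'M', got {self.sex!r}")
        for name in ("age", "systolic_bp", "total_chol", "hdl_chol"):
            v = getattr(self, name)
            if not (v is not None and np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")
        if self.hdl_chol >= self.total_chol:
            raise ValueError(
                f"hdl_chol ({self.hdl_chol}) must be below total_chol ({self.total_chol})"
            )
        if self.cigarettes_per_day < 0:
            raise ValueError("cigarettes_per_day must be >= 0")
        if not self.smoker and self.cigarettes_per_day != 0:
            raise ValueError("cigarettes_per_day must be 0 for non-smokers")
        if self.simd is not None and not (0 <= self.simd <= 100):
            raise ValueError(f"simd must lie in [0, 100], got {self.simd}")

    def as_dict(self) -> dict[str, float | bool | None]:
        return {
            "age": self.age,
            "systolic_bp": self.systolic_bp,
            "total_chol": self.total_chol,
            "hdl_chol": self.hdl_chol,
            "cigarettes_per_day": self.cigarettes_per_day,
            "simd": self.simd,
            "smoker": self.smoker,
            "diabetes": self.diabetes,
            "family_history_cvd": self.family_history_cvd,
            "bp_treated": self.bp_treated,
            "rheumatoid_arthritis": self.rheumatoid_arthritis,
        }


@dataclass(frozen=True)
class Factor:
    """One multiplicative factor of a term: a transform of a raw covariate."""

    covariate: str
    kind: str = "identity"  # identity | affine | log | indicator
    a: float = 1.0
    b: float = 0.0
    equals: bool | float = True  # indicator condition

    def __post_init__(self):
        if self.covariate not in COVARIATE_NAMES:
            raise ModelSpecError(f"unknown covariate {self.covariate!r} in factor")
        if self.kind not in ("identity", "affine", "log", "indicator"):
            raise ModelSpecError(f"unknown transform {self.kind!r} for {self.covariate!r}")

    def evaluate(self, x):
        """Vectorised transform; NaN propagates, log of non-positive -> NaN."""
        x = np.asarray(x, dtype=float)
        if self.kind == "identity":
            return x
        if self.kind == "affine":
            return self.a * x + self.b
        if self.kind == "log":
            with np.errstate(invalid="ignore", divide="ignore"):
                out = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
            return out
        # indicator: exact equality against the condition value (booleans are
        # stored as 0/1 floats); NaN stays NaN so missingness can be flagged
        target = float(self.equals)
        out = np.where(np.isnan(x), np.nan, (x == target).astype(float))
        return out


@dataclass(frozen=True)
class TermDefinition:
    """Named product of factors; the term's value enters lp weighted by beta."""

    name: str
    factors: tuple[Factor, ...]

    def __post_init__(self):
        if not self.factors:
            raise ModelSpecError(f"term {self.name!r} has no factors")

    @property
    def covariates(self) -> set[str]:
        return {f.covariate for f in self.factors}

    def evaluate(self, values: Mapping[str, object]):
        out = None
        for f in self.factors:
            if f.covariate not in values:
                raise ValueError(
                    f"term {self.name!r} references missing covariate {f.covariate!r}"
                )
            v = values[f.covariate]
            if v is None:
                v = np.nan
            x = f.evaluate(np.asarray(v, dtype=float))
            out = x if out is None else out * x
        return out


@dataclass(frozen=True)
class SexModel:
    terms: tuple[TermDefinition, ...]
    coefficients: dict[str, float]
    centering_constant: float
    baseline_survival_10y: float

    def validate(self, sex: str) -> None:
        term_names = [t.name for t in self.terms]
        if len(set(term_names)) != len(term_names):
            raise ModelSpecError(f"{sex}: duplicate term names")
        if set(term_names) != set(self.coefficients):
            missing = set(term_names) ^ set(self.coefficients)
            raise ModelSpecError(
                f"{sex}: terms and coefficients are not in bijection (mismatch: {sorted(missing)})"
            )
        s0 = self.baseline_survival_10y
        if not (0.0 < s0 < 1.0):
            raise ModelSpecError(
                f"{sex}: baseline_survival_10y must lie in (0, 1), got {s0}"
            )
        if not np.isfinite(self.centering_constant):
            raise ModelSpecError(f"{sex}: centering_constant must be finite")


@dataclass(frozen=True)
class RiskModelSpec:
    """A declarative 10-year survival risk equation (both sexes)."""

    model_name: str
    endpoint_id: str
    sex_models: dict[str, SexModel]
    cholesterol_units: str = "mmol/L"
    valid_age_range: tuple[float, float] | None = None

    def validate(self) -> None:
        for sex in SEXES:
            if sex not in self.sex_models:
                raise ModelSpecError(f"model {self.model_name!r}: missing {sex!r} block")
            self.sex_models[sex].validate(sex)
        if self.cholesterol_units not in ("mmol/L", "mg/dL"):
            raise ModelSpecError(
                f"unknown cholesterol unit system {self.cholesterol_units!r}"
            )

    def for_sex(self, sex: str) -> SexModel:
        key = {"F": "female", "M": "male"}.get(sex, sex)
        return self.sex_models[key]

    @property
    def required_covariates(self) -> set[str]:
        out: set[str] = set()
        for sm in self.sex_models.values():
            for t in sm.terms:
                out |= t.covariates
        return out

    def with_baseline_survival(self, s0_by_sex: Mapping[str, float]) -> "RiskModelSpec":
        """Copy of the spec with updated S0(10) per sex (recalibration)."""
        new = dict(self.sex_models)
        for sex, s0 in s0_by_sex.items():
            if not (0.0 < s0 < 1.0):
                raise ModelSpecError(f"updated S0 for {sex} outside (0,1): {s0}")
            new[sex] = replace(new[sex], baseline_survival_10y=float(s0))
        return replace(self, sex_models=new)


# ---------------------------------------------------------------------------
# spec files


def _parse_factor(d: Mapping, where: str) -> Factor:
    if "covariate" not in d:
        raise ModelSpecError(f"{where}: factor missing 'covariate'")
    return Factor(
        covariate=d["covariate"],
        kind=d.get("transform", "identity"),
        a=float(d.get("a", 1.0)),
        b=float(d.get("b", 0.0)),
        equals=d.get("equals", True),
    )


def _parse_sex_model(block: Mapping, where: str) -> SexModel:
    for key in ("terms", "coefficients", "baseline_survival_10y"):
        if key not in block:
            raise ModelSpecError(f"{where}: missing required field {key!r}")
    terms = []
    for t in block["terms"]:
        if "name" not in t or "factors" not in t:
            raise ModelSpecError(f"{where}: every term needs 'name' and 'factors'")
        terms.append(
            TermDefinition(
                name=t["name"],
                factors=tuple(
                    _parse_factor(f, f"{where}.{t['name']}") for f in t["factors"]
                ),
            )
        )
    return SexModel(
        terms=tuple(terms),
        coefficients={k: float(v) for k, v in block["coefficients"].items()},
        centering_constant=float(block.get("centering_constant", 0.0)),
        baseline_survival_10y=float(block["baseline_survival_10y"]),
    )


def load_model_spec(path: str | Path) -> RiskModelSpec:
    """Load and validate a YAML/JSON risk-model specification file."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ModelSpecError(f"{path}: top level must be a mapping")
    for key in ("model_name", "endpoint"):
        if key not in raw:
            raise ModelSpecError(f"{path}: missing required field {key!r}")
    sex_models = {}
    for sex in SEXES:
        if sex not in raw:
            raise ModelSpecError(f"{path}: missing {sex!r} coefficient block")
        sex_models[sex] = _parse_sex_model(raw[sex], f"{raw['model_name']}.{sex}")
    age_range = raw.get("valid_age_range")
    spec = RiskModelSpec(
        model_name=raw["model_name"],
        endpoint_id=raw["endpoint"],
        sex_models=sex_models,
        cholesterol_units=raw.get("units", {}).get("cholesterol", "mmol/L"),
        valid_age_range=tuple(age_range) if age_range else None,
    )
    spec.validate()
    return spec


def load_packaged_spec(name: str) -> RiskModelSpec:
    """Load one of the shipped model specs: 'assign', 'score2' or 'pce'."""
    from importlib.resources import files

    path = files("deprisk.data") / f"{name}.yaml"
    if not path.is_file():
        raise ModelSpecError(f"no packaged model spec named {name!r}")
    return load_model_spec(str(path))


# ---------------------------------------------------------------------------
# evaluation


def linear_predictor(profile: CovariateProfile, spec: RiskModelSpec) -> float:
    """lp = sum_k beta_k * term_k(profile) for the profile's sex."""
    sm = spec.for_sex(profile.sex)
    values = profile.as_dict()
    lp = 0.0
    for term in sm.terms:
        v = float(term.evaluate(values))
        if not math.isfinite(v):
            raise ValueError(
                f"term {term.name!r} evaluated to a non-finite value for this profile"
            )
        lp += sm.coefficients[term.name] * v
    if spec.valid_age_range is not None:
        lo, hi = spec.valid_age_range
        if not (lo <= profile.age <= hi):
            logger.warning(
                "%s: age %.1f outside derivation range [%g, %g]; scored without clamping",
                spec.model_name,
                profile.age,
                lo,
                hi,
            )
    return lp


def ten_year_risk(lp, spec: RiskModelSpec, sex: str):
    """risk = 1 - S0(10)**exp(lp - c); strictly increasing in lp."""
    sm = spec.for_sex(sex)
    lp = np.asarray(lp, dtype=float)
    if not np.all(np.isfinite(lp)):
        raise ValueError("linear predictor must be finite")
    out = 1.0 - sm.baseline_survival_10y ** np.exp(lp - sm.centering_constant)
    return float(out) if out.ndim == 0 else out


def predict_risk(profile: CovariateProfile, spec: RiskModelSpec) -> float:
    return ten_year_risk(linear_predictor(profile, spec), spec, profile.sex)


@dataclass
class ScoreResult:
    """Per-participant predictions for one cohort/model pair.

    ``flagged`` marks rows that could not be scored (missing required
    covariate, non-finite term); their lp/risk entries are NaN. Flagged rows
    are never dropped: index alignment with the cohort is preserved.
    """

    lp: np.ndarray
    risk: np.ndarray
    flagged: np.ndarray
    model_name: str

    @property
    def n(self) -> int:
        return len(self.risk)

    @property
    def n_scored(self) -> int:
        return int((~self.flagged).sum())

    @property
    def n_flagged(self) -> int:
        return int(self.flagged.sum())


_BOOL_COLUMNS = ("smoker", "diabetes", "family_history_cvd", "bp_treated",
                 "rheumatoid_arthritis")


def _column_values(cohort: pd.DataFrame, name: str) -> np.ndarray:
    col = cohort[name]
    if name in _BOOL_COLUMNS:
        # accept bool, 0/1, or missing
        return col.astype("float64").to_numpy()
    return pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)


def score_cohort(cohort: pd.DataFrame, spec: RiskModelSpec) -> ScoreResult:
    """Score every participant; missing-covariate rows are flagged, not dropped."""
    if len(cohort) == 0:
        raise ValueError("cannot score an empty cohort")
    if "sex" not in cohort.columns:
        raise ValueError("cohort is missing the 'sex' column")
    needed = spec.required_covariates
    missing_cols = sorted(needed - set(cohort.columns))
    if missing_cols:
        raise ValueError(
            f"cohort lacks columns required by {spec.model_name!r}: {missing_cols}"
        )
    n = len(cohort)
    lp = np.full(n, np.nan)
    risk = np.full(n, np.nan)
    flagged = np.zeros(n, dtype=bool)
    sex_col = cohort["sex"].astype(str).to_numpy()
    values = {name: _column_values(cohort, name) for name in needed}
    for sex_code, sex_key in (("F", "female"), ("M", "male")):
        mask = sex_col == sex_code
        if not mask.any():
            continue
        sm = spec.sex_models[sex_key]
        sub = {k: v[mask] for k, v in values.items()}
        lp_s = np.zeros(int(mask.sum()))
        with np.errstate(invalid="ignore"):
            for term in sm.terms:
                lp_s = lp_s + sm.coefficients[term.name] * np.asarray(
                    term.evaluate(sub), dtype=float
                )
        bad = ~np.isfinite(lp_s)
        risk_s = np.where(
            bad,
            np.nan,
            1.0
            - sm.baseline_survival_10y
            ** np.exp(np.where(bad, 0.0, lp_s) - sm.centering_constant),
        )
        lp[mask] = np.where(bad, np.nan, lp_s)
        risk[mask] = risk_s
        flagged[mask] = bad
    unknown_sex = ~np.isin(sex_col, ["F", "M"])
    flagged |= unknown_sex
    if spec.valid_age_range is not None and "age" in cohort.columns:
        lo, hi = spec.valid_age_range
        ages = pd.to_numeric(cohort["age"], errors="coerce")
        n_out = int(((ages < lo) | (ages > hi)).sum())
        if n_out:
            logger.warning(
                "%s: %d participants outside derivation age range [%g, %g]; "
                "scored without clamping",
                spec.model_name, n_out, lo, hi,
            )
    logger.info(
        "%s: scored %d/%d participants (%d flagged unscorable)",
        spec.model_name, n - int(flagged.sum()), n, int(flagged.sum()),
    )
    return ScoreResult(lp=lp, risk=risk, flagged=flagged, model_name=spec.model_name)


# ---------------------------------------------------------------------------
# units


def convert_units(obj, from_system: str, to_system: str):
    """Convert cholesterol units (mmol/L <-> mg/dL) of a profile or cohort.

    Returns a converted copy; every non-cholesterol field is untouched.
    """
    for s in (from_system, to_system):
        if s not in ("mmol/L", "mg/dL"):
            raise ValueError(f"unknown unit system {s!r}")
    if from_system == to_system:
        factor = 1.0
    elif from_system == "mmol/L":
        factor = CHOL_MMOL_TO_MGDL
    else:
        factor = 1.0 / CHOL_MMOL_TO_MGDL
    if isinstance(obj, CovariateProfile):
        return replace(
            obj,
            total_chol=obj.total_chol * factor,
            hdl_chol=obj.hdl_chol * factor,
        )
    if isinstance(obj, pd.DataFrame):
        out = obj.copy()
        for col in ("total_chol", "hdl_chol"):
            if col in out.columns:
                out[col] = pd.to_numeric(out[col], errors="coerce") * factor
        return out
    raise TypeError(f"cannot convert units of {type(obj).__name__}")
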