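"""End-to-end orchestration: simulate/load -> score -> recalibrate ->
evaluate -> refit -> report, plus the CSV readers/writers.

File contracts
--------------
Cohort CSV: one row per participant; columns ``id, sex`` (F/M), the raw
covariates (``age, systolic_bp, total_chol, hdl_chol, smoker,
cigarettes_per_day, diabetes, family_history_cvd, bp_treated, simd`` ...),
and either per-participant follow-up (``time_years, status``) or
``admin_censor_years`` for follow-up built from an events file. Missing
values are empty cells, never zeros. Events CSV: ``participant_id,
time_years, code_system, code, fatal``; ISO-8601 ``event_date`` is accepted
when the cohort carries ``baseline_date``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import (
    CalibrationReport,
    RecalibrationResult,
    recalibrate_s0,
    refit_with_deprivation,
    stratified_report,
)
from .deprivation import DeprivationConfig
from .endpoints import CODE_SYSTEMS, build_follow_up_table, load_endpoint_specs
from .models import RiskModelSpec, convert_units, load_model_spec, load_packaged_spec, score_cohort
from .simulate import SimulationConfig, simulate_cohort
from .survival import SurvivalSample

logger = logging.getLogger(__name__)

PACKAGED_MODELS = ("assign", "score2", "pce")

_BOOL_COLS = ("smoker", "diabetes", "family_history_cvd", "bp_treated",
              "rheumatoid_arthritis")
_TRUE = {"1", "1.0", "true", "t", "yes", "y"}
_FALSE = {"0", "0.0", "false", "f", "no", "n", ""}


class ValidationError(ValueError):
    """Input file failed schema validation."""


def _parse_bool_column(col: pd.Series, name: str) -> pd.Series:
    out = []
    for i, v in enumerate(col):
        if pd.isna(v):
            out.append(np.nan)
            continue
        s = str(v).strip().lower()
        if s in _TRUE:
            out.append(1.0)
        elif s in _FALSE:
            out.append(np.nan if s == "" else 0.0)
        else:
            raise ValidationError(
                f"column {name!r}, row {i + 2}: cannot interpret {v!r} as boolean"
            )
    return pd.Series(out, index=col.index, dtype=float)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV (empty cells become missing values)."""
    df = pd.read_csv(path, dtype={"id": str, "sex": str})
    for col in ("id", "sex"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    bad_sex = ~df["sex"].isin(["F", "M"])
    if bad_sex.any():
        row = int(np.flatnonzero(bad_sex)[0])
        raise ValidationError(
            f"{path}: row {row + 2}: sex must be 'F' or 'M', got "
            f"{df['sex'].iloc[row]!r}"
        )
    if df["id"].duplicated().any():
        dup = df["id"][df["id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate participant id {dup!r}")
    for col in _BOOL_COLS:
        if col in df.columns:
            df[col] = _parse_bool_column(df[col], col)
    for col in df.columns:
        if col in ("id", "sex", "baseline_date"):
            continue
        df[col] = pd.to_numeric(df[col], errors="coerce")
    if "time_years" in df.columns:
        nonpos = df["time_years"] <= 0
        if nonpos.any():
            row = int(np.flatnonzero(nonpos)[0])
            raise ValidationError(
                f"{path}: row {row + 2}: time_years must be > 0"
            )
    return df


def read_events(path: str | Path, cohort: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read and validate an events CSV; dates are converted to years on load."""
    df = pd.read_csv(path, dtype={"participant_id": str, "code": str})
    for col in ("participant_id", "code_system", "code"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if "time_years" not in df.columns:
        if "event_date" in df.columns and cohort is not None and "baseline_date" in cohort.columns:
            base = cohort.set_index("id")["baseline_date"]
            t0 = pd.to_datetime(df["participant_id"].map(base), format="ISO8601")
            t1 = pd.to_datetime(df["event_date"], format="ISO8601")
            df["time_years"] = (t1 - t0).dt.days / 365.25
        else:
            raise ValidationError(
                f"{path}: needs 'time_years' (or 'event_date' plus a cohort "
                f"'baseline_date' column)"
            )
    df["time_years"] = pd.to_numeric(df["time_years"], errors="raise")
    bad = ~df["code_system"].isin(CODE_SYSTEMS)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValidationError(
            f"{path}: row {row + 2}: unknown code system "
            f"{df['code_system'].iloc[row]!r}"
        )
    if (df["time_years"] < 0).any():
        row = int(np.flatnonzero(df["time_years"] < 0)[0])
        raise ValidationError(f"{path}: row {row + 2}: negative event time")
    df["fatal"] = (
        _parse_bool_column(df["fatal"], "fatal").fillna(0).astype(bool)
        if "fatal" in df.columns
        else False
    )
    return df


# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration of one validation run (exactly one input source)."""

    cohort_path: str | None = None
    events_path: str | None = None
    simulation: SimulationConfig | None = None
    models: tuple = ("assign", "score2", "pce")
    recalibrate: bool = True
    refit: bool = True
    horizon: float = 10.0
    output_dir: str | None = None
    seed: int = 1
    complete_case: bool = True
    single_impute: bool = False  # labelled deviation: mean/mode single imputation
    cohort_cholesterol_units: str = "mmol/L"
    deprivation: DeprivationConfig = field(default_factory=DeprivationConfig)

    def validate(self) -> None:
        has_files = self.cohort_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValidationError(
                "exactly one of cohort_path and simulation must be given"
            )
        if self.horizon <= 0:
            raise ValidationError("horizon must be > 0")


@dataclass
class ModelRunResult:
    model_name: str
    raw_report: CalibrationReport
    recalibrated_report: CalibrationReport | None
    recalibration: RecalibrationResult | None
    refit: dict | None
    n_flagged: int


def _resolve_spec(model) -> RiskModelSpec:
    if isinstance(model, RiskModelSpec):
        return model
    if model in PACKAGED_MODELS:
        return load_packaged_spec(model)
    return load_model_spec(model)


def _single_impute(cohort: pd.DataFrame, needed: set[str]) -> pd.DataFrame:
    """Mean/mode single imputation for non-deprivation covariates.

    A deliberately simple stand-in for a chained-equations procedure; SIMD is
    never imputed, so deprivation strata only ever contain observed scores.
    """
    out = cohort.copy()
    for col in needed:
        if col == "simd" or col not in out.columns:
            continue
        if col in _BOOL_COLS or col == "cigarettes_per_day":
            fill = out[col].mode(dropna=True)
            if len(fill):
                out[col] = out[col].fillna(fill.iloc[0])
        else:
            out[col] = out[col].fillna(out[col].mean())
    return out


def _follow_up_for(
    cohort: pd.DataFrame,
    events: pd.DataFrame | None,
    endpoint_id: str,
    endpoint_specs: dict,
) -> pd.DataFrame:
    if events is not None and endpoint_id in endpoint_specs:
        participants = cohort[["id"]].copy()
        if "admin_censor_years" not in cohort.columns:
            raise ValidationError(
                "cohort needs 'admin_censor_years' to build follow-up from events"
            )
        participants["admin_censor_years"] = cohort["admin_censor_years"]
        return build_follow_up_table(events, participants, endpoint_specs[endpoint_id])
    if "time_years" not in cohort.columns or "status" not in cohort.columns:
        raise ValidationError(
            f"no events available for endpoint {endpoint_id!r} and the cohort "
            f"carries no time_years/status columns"
        )
    return pd.DataFrame(
        {"time": cohort["time_years"], "status": cohort["status"].astype(int)},
        index=cohort.index,
    )


def run_model(
    cohort: pd.DataFrame,
    events: pd.DataFrame | None,
    model,
    config: RunConfig,
    endpoint_specs: dict,
) -> ModelRunResult:
    """Score one model on the cohort and produce raw/recalibrated reports."""
    spec = _resolve_spec(model)
    follow_up = _follow_up_for(cohort, events, spec.endpoint_id, endpoint_specs)
    work = cohort
    if config.single_impute and not config.complete_case:
        work = _single_impute(work, spec.required_covariates)
    if spec.cholesterol_units != config.cohort_cholesterol_units:
        work = convert_units(
            work, config.cohort_cholesterol_units, spec.cholesterol_units
        )
    scores = score_cohort(work, spec)
    raw = stratified_report(
        work, scores, follow_up, recalibrated=False,
        horizon=config.horizon, dep_config=config.deprivation,
    )
    recal_report = None
    recal_result = None
    if config.recalibrate:
        sex_col = work["sex"].astype(str).to_numpy()
        usable = ~scores.flagged
        lp_by_sex, fu_by_sex = {}, {}
        for code, key in (("F", "female"), ("M", "male")):
            m = usable & (sex_col == code)
            lp_by_sex[key] = scores.lp[m]
            fu_by_sex[key] = SurvivalSample(
                follow_up["time"].to_numpy()[m], follow_up["status"].to_numpy()[m]
            )
        recal_result = recalibrate_s0(lp_by_sex, fu_by_sex, spec, config.horizon)
        recal_spec = spec.with_baseline_survival(recal_result.updated_s0)
        recal_scores = score_cohort(work, recal_spec)
        recal_report = stratified_report(
            work, recal_scores, follow_up, recalibrated=True,
            horizon=config.horizon, dep_config=config.deprivation,
        )
    refit = None
    if config.refit and "simd" in work.columns and work["simd"].notna().any():
        fits = refit_with_deprivation(work, spec, follow_up)
        refit = {}
        for sex, fit in fits.items():
            from .calibration import deprivation_term_name

            term = deprivation_term_name(fit)
            hr, lo, hi = fit.hr_with_ci(term)
            refit[sex] = {
                "deprivation_term": term,
                "log_hr": float(fit.coef[term]),
                "hr": hr,
                "hr_ci_low": lo,
                "hr_ci_high": hi,
                "n": fit.n,
                "events": fit.n_events,
                "coefficients": {k: float(v) for k, v in fit.coef.items()},
            }
    return ModelRunResult(
        model_name=spec.model_name,
        raw_report=raw,
        recalibrated_report=recal_report,
        recalibration=recal_result,
        refit=refit,
        n_flagged=scores.n_flagged,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the full validation for every configured model.

    Returns ``{"manifest": ..., "models": {name: ModelRunResult}}`` and, when
    ``config.output_dir`` is set, writes JSON reports, CSV tables and a run
    manifest there.
    """
    config.validate()
    if config.simulation is not None:
        sim = simulate_cohort(config.simulation.replace(seed=config.seed))
        cohort, events = sim.cohort, sim.events
        source = f"simulated(n={config.simulation.n}, seed={config.seed})"
    else:
        cohort = read_cohort(config.cohort_path)
        events = read_events(config.events_path, cohort) if config.events_path else None
        source = str(config.cohort_path)
    endpoint_specs = load_endpoint_specs()
    results: dict[str, ModelRunResult] = {}
    for model in config.models:
        name = model if isinstance(model, str) else model.model_name
        logger.info("running model %s", name)
        try:
            results[name] = run_model(cohort, events, model, config, endpoint_specs)
        except Exception as err:
            raise RuntimeError(
                f"stage 'model:{name}' failed on cohort of n={len(cohort)}: {err}"
            ) from err
    manifest = {
        "deprisk_version": __version__,
        "seed": config.seed,
        "horizon_years": config.horizon,
        "source": source,
        "models": [
            m if isinstance(m, str) else m.model_name for m in config.models
        ],
        "recalibrate": config.recalibrate,
        "complete_case": config.complete_case,
        "single_impute": config.single_impute,
        "n_participants": int(len(cohort)),
        "config_hash": _config_hash(config),
    }
    out = {"manifest": manifest, "models": results}
    if config.output_dir:
        write_outputs(out, config.output_dir)
    return out


def _config_hash(config: RunConfig) -> str:
    payload = {
        k: (v if isinstance(v, (str, int, float, bool, tuple, list, type(None))) else str(v))
        for k, v in vars(config).items()
    }
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# writers


def _round4(df: pd.DataFrame) -> pd.DataFrame:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(4)
    return out


def write_report(report: CalibrationReport, outdir: str | Path) -> list[Path]:
    """Write one calibration report as JSON, a summary CSV and decile CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{report.model_name}_{'recalibrated' if report.recalibrated else 'raw'}"
    written = []
    jpath = outdir / f"{tag}.json"
    with open(jpath, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    written.append(jpath)
    spath = outdir / f"{tag}_summary.csv"
    _round4(report.summary_frame()).to_csv(spath, index=False)
    written.append(spath)
    for name, stratum in report.strata.items():
        if stratum.deciles is not None:
            dpath = outdir / f"{tag}_deciles_{name}.csv"
            _round4(stratum.deciles).to_csv(dpath, index=False)
            written.append(dpath)
    return written


def write_outputs(result: dict, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result["manifest"], fh, indent=2)
    for name, res in result["models"].items():
        write_report(res.raw_report, outdir)
        if res.recalibrated_report is not None:
            write_report(res.recalibrated_report, outdir)
        extra = {
            "model": name,
            "n_flagged_unscorable": res.n_flagged,
            "recalibration": res.recalibration.to_dict() if res.recalibration else None,
            "deprivation_refit": res.refit,
        }
        with open(outdir / f"{name}_recalibration_refit.json", "w") as fh:
            json.dump(extra, fh, indent=2)
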