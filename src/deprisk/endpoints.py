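"""ICD-10 / OPCS-4 endpoint definitions and time-to-first-event construction.

Each risk score validates against its own composite cardiovascular outcome,
defined by code lists over three record systems: hospital diagnoses
(ICD-10), underlying cause of death (ICD-10) and procedures (OPCS-4). Code
expressions follow the conventions of published score definitions:

* ``"I51.4"`` — one exact code (category + subcode);
* ``"I21"`` — a 3-character category, matching the category itself and every
  subcode (``I21.x``);
* ``"I21-I22"`` or the short form ``"K40-46"`` — an inclusive category range;
* ``"R96.0-R96.1"`` — a subcode range inside one category.

Non-endpoint deaths censor follow-up (the Kaplan–Meier convention for
observed risks); competing-risk estimators are out of scope.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

CODE_SYSTEMS = ("icd10_diagnosis", "icd10_cause_of_death", "opcs4_procedure")

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.(\d+))?$")


class CodeExpressionError(ValueError):
    """Raised for a malformed code or code-range expression."""


def _parse_code(code: str, expr: str):
    m = _CODE_RE.match(code.strip().upper())
    if not m:
        raise CodeExpressionError(f"malformed code {code!r} in expression {expr!r}")
    letter, num, sub = m.groups()
    return letter, int(num), sub


def code_matches(code: str, range_expr: str) -> bool:
    """True iff *code* falls inside the code/range expression.

    Category-level expressions match by prefix (``I21`` matches ``I21.4``);
    subcode-level expressions match subcodes exactly.
    """
    expr = range_expr.strip().replace("–", "-").replace("—", "-")
    if not expr:
        raise CodeExpressionError("empty code expression")
    c_letter, c_num, c_sub = _parse_code(code, expr)
    if "-" not in expr:
        e_letter, e_num, e_sub = _parse_code(expr, expr)
        if (c_letter, c_num) != (e_letter, e_num):
            return False
        if e_sub is None:  # category expression: prefix match
            return True
        return c_sub == e_sub
    lo, _, hi = expr.partition("-")
    lo = lo.strip()
    hi = hi.strip()
    l_letter, l_num, l_sub = _parse_code(lo, expr)
    # short form second half: "K40-46" or "R96.0-.1" style digits
    if re.fullmatch(r"\d{2}(?:\.\d+)?", hi):
        hi = l_letter + hi
    h_letter, h_num, h_sub = _parse_code(hi, expr)
    if l_letter != h_letter:
        raise CodeExpressionError(f"range {range_expr!r} spans chapters")
    if (l_sub is None) != (h_sub is None):
        raise CodeExpressionError(
            f"range {range_expr!r} mixes category and subcode endpoints"
        )
    if l_sub is None:
        if (l_letter, l_num) > (h_letter, h_num):
            raise CodeExpressionError(f"range {range_expr!r} is reversed")
        return c_letter == l_letter and l_num <= c_num <= h_num
    # subcode range: confined to one category
    if l_num != h_num:
        raise CodeExpressionError(
            f"subcode range {range_expr!r} must stay within one category"
        )
    if c_sub is None:
        return False
    return (c_letter, c_num) == (l_letter, l_num) and l_sub <= c_sub <= h_sub


@dataclass(frozen=True)
class EventRecord:
    """One coded clinical event for a participant."""

    participant_id: str
    time: float  # years since baseline
    code_system: str
    code: str
    fatal: bool = False

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"event time must be >= 0, got {self.time}")
        if self.code_system not in CODE_SYSTEMS:
            raise ValueError(f"unknown code system {self.code_system!r}")
        if self.fatal and self.code_system != "icd10_cause_of_death":
            raise ValueError("fatal=True is only valid for cause-of-death records")


@dataclass(frozen=True)
class EndpointComponent:
    code_system: str
    include: tuple[str, ...]
    exclude: tuple[str, ...] = ()
    fatal_required: str = "either"  # yes | no | either

    def matches(self, event: EventRecord) -> bool:
        if event.code_system != self.code_system:
            return False
        if self.fatal_required == "yes" and not event.fatal:
            return False
        if self.fatal_required == "no" and event.fatal:
            return False
        if not any(code_matches(event.code, r) for r in self.include):
            return False
        return not any(code_matches(event.code, r) for r in self.exclude)


@dataclass(frozen=True)
class EndpointSpec:
    """A composite outcome: union of components over the three code systems."""

    endpoint_id: str
    components: tuple[EndpointComponent, ...]

    def validate(self) -> None:
        if not self.components:
            raise ValueError(f"endpoint {self.endpoint_id!r} has no components")
        for comp in self.components:
            if comp.code_system not in CODE_SYSTEMS:
                raise ValueError(
                    f"{self.endpoint_id}: unknown code system {comp.code_system!r}"
                )
            if comp.fatal_required not in ("yes", "no", "either"):
                raise ValueError(
                    f"{self.endpoint_id}: fatal_required must be yes/no/either"
                )
            for rng in comp.include + comp.exclude:
                code_matches("A00", rng)  # parse check only
            for excl in comp.exclude:
                probe = excl if "." in excl else excl  # exclusions are single codes
                if not any(code_matches(probe, rng) for rng in comp.include):
                    raise ValueError(
                        f"{self.endpoint_id}: exclusion {excl!r} lies outside every "
                        f"inclusion range of its component"
                    )


def classify_event(event: EventRecord, spec: EndpointSpec) -> bool:
    """True iff the event qualifies for the endpoint's composite outcome."""
    return any(comp.matches(event) for comp in spec.components)


@dataclass(frozen=True)
class FollowUpRecord:
    participant_id: str
    time: float
    status: int  # 1 = endpoint event, 0 = censored

    def __post_init__(self):
        if self.time <= 0:
            raise ValueError("follow-up time must be > 0")
        if self.status not in (0, 1):
            raise ValueError("status must be 0 or 1")


def build_follow_up(
    events: Sequence[EventRecord],
    spec: EndpointSpec,
    admin_censor_time: float | None,
    non_endpoint_death_time: float | None = None,
    participant_id: str = "",
) -> FollowUpRecord:
    """Time to first qualifying event, else censoring at the earliest of
    administrative end of follow-up and non-endpoint death."""
    censor_candidates = [
        t for t in (admin_censor_time, non_endpoint_death_time) if t is not None
    ]
    if not censor_candidates and not events:
        raise ValueError("no events and no censoring time: follow-up undefined")
    t_cens = min(censor_candidates) if censor_candidates else float("inf")
    qualifying = sorted(e.time for e in events if classify_event(e, spec))
    if qualifying and qualifying[0] <= t_cens:
        pid = participant_id or (events[0].participant_id if events else "")
        return FollowUpRecord(pid, qualifying[0], 1)
    if not censor_candidates:
        raise ValueError("no qualifying events and no censoring time")
    pid = participant_id or (events[0].participant_id if events else "")
    return FollowUpRecord(pid, t_cens, 0)


def build_follow_up_table(
    events: pd.DataFrame,
    participants: pd.DataFrame,
    spec: EndpointSpec,
) -> pd.DataFrame:
    """Vectorised follow-up construction for a whole cohort.

    ``events`` columns: participant_id, time_years, code_system, code, fatal.
    ``participants`` columns: id, admin_censor_years. Deaths whose cause does
    not qualify censor at the death time. Returns a frame indexed like
    ``participants`` with columns ``time`` and ``status``.
    """
    ev = events.copy()
    if len(ev):
        # classify unique (system, code, fatal) triples once
        keys = ev[["code_system", "code", "fatal"]].drop_duplicates()
        qual = {
            (r.code_system, r.code, bool(r.fatal)): classify_event(
                EventRecord("x", 0.0, r.code_system, r.code, bool(r.fatal)), spec
            )
            for r in keys.itertuples()
        }
        ev["qualifies"] = [
            qual[(s, c, bool(f))]
            for s, c, f in zip(ev["code_system"], ev["code"], ev["fatal"])
        ]
        first_event = (
            ev[ev["qualifies"]].groupby("participant_id")["time_years"].min()
        )
        deaths = ev[(ev["fatal"]) & (~ev["qualifies"])]
        death_time = deaths.groupby("participant_id")["time_years"].min()
    else:
        first_event = pd.Series(dtype=float)
        death_time = pd.Series(dtype=float)
    ids = participants["id"].astype(str)
    t_event = ids.map(first_event).to_numpy(dtype=float)
    t_death = ids.map(death_time).to_numpy(dtype=float)
    t_admin = pd.to_numeric(participants["admin_censor_years"]).to_numpy(dtype=float)
    import numpy as np

    t_cens = np.fmin(t_admin, t_death)
    has_event = ~np.isnan(t_event) & (t_event <= t_cens)
    time = np.where(has_event, t_event, t_cens)
    return pd.DataFrame(
        {"time": time, "status": has_event.astype(int)}, index=participants.index
    )


# ---------------------------------------------------------------------------
# packaged endpoint definitions


def load_endpoint_specs(path: str | Path | None = None) -> dict[str, EndpointSpec]:
    """Load endpoint definitions (packaged file when *path* is omitted)."""
    if path is None:
        from importlib.resources import files

        path = str(files("deprisk.data") / "endpoints.yaml")
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    specs: dict[str, EndpointSpec] = {}
    for endpoint_id, block in raw.items():
        comps = tuple(
            EndpointComponent(
                code_system=c["code_system"],
                include=tuple(str(x) for x in c["include"]),
                exclude=tuple(str(x) for x in c.get("exclude", ())),
                fatal_required=c.get("fatal", "either"),
            )
            for c in block["components"]
        )
        spec = EndpointSpec(endpoint_id=endpoint_id, components=comps)
        spec.validate()
        specs[endpoint_id] = spec
    return specs
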