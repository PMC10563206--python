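"""Forward rule matcher and warning post-processing.

The engine pipeline, per surveillance case:

1. **match** — a rule fires iff *every* condition evaluates true on the
   case (conditions on missing factors are false: a rule cannot fire on
   unknown data);
2. **select** — when several rules fire for the same diagnosis, only the
   highest-probability one is kept (ties broken by lowest rule id);
3. **onset** — warnings whose case lies at most 48 h (configurable)
   after admission are labelled ``community_acquired``;
4. **thresholds** — warnings whose probability falls strictly below the
   per-diagnosis threshold are labelled ``below_threshold`` and not sent;
5. **repeat-infection timeframe (RTI)** — a warning for a patient/site
   already alerted within the previous 14 days (configurable) is
   labelled ``suppressed_rti``.

Every fired rule leaves the pipeline with an explicit status, so each
exclusion is auditable; nothing is silently dropped.

Boundary semantics are fixed and documented: strictly-greater-than for
the onset cutoff (onset at exactly 48 h counts as community-acquired),
strictly-less-than for threshold rejection, half-open ``[low, high)``
ranges, and strictly-less-than the RTI window length for suppression.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .cases import CaseTuple, GoldLabel
from .rules import Condition, KnowledgeRule, RuleBase, SCENARIOS, filter_by_source

__all__ = [
    "STATUSES",
    "FiredRule",
    "WarningResult",
    "EngineConfig",
    "evaluate_condition",
    "match_rules",
    "select_per_diagnosis",
    "classify_onset",
    "apply_thresholds",
    "apply_rti",
    "run_surveillance",
    "write_warnings_csv",
    "read_warnings_csv",
    "write_warnings_jsonl",
]

STATUSES = ("alerted", "suppressed_rti", "below_threshold", "community_acquired")


@dataclass(frozen=True)
class FiredRule:
    rule_id: str
    diagnosis_code: str
    site_code: str
    probability: float
    patient_id: str
    episode_id: str
    as_of_date: dt.date


@dataclass
class WarningResult:
    """One infection warning with its post-processing status."""

    patient_id: str
    episode_id: str
    infection_time: dt.date
    site_code: str
    diagnosis_code: str
    probability: float
    rule_id: str
    status: str = "alerted"

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "episode_id": self.episode_id,
            "infection_time": self.infection_time.isoformat(),
            "site_code": self.site_code,
            "diagnosis_code": self.diagnosis_code,
            "probability": self.probability,
            "rule_id": self.rule_id,
            "status": self.status,
        }


@dataclass
class EngineConfig:
    """Tunables of the post-processing pipeline.

    rti_days: repeat-infection timeframe, days (default 14, per clinical
        guideline practice).
    onset_cutoff_hours: hours after admission separating community- from
        hospital-acquired onset (default 48; onset strictly beyond the
        cutoff is hospital-acquired).
    thresholds: per-diagnosis minimum probability; unconfigured
        diagnoses default to 0 (always pass).
    rti_key: "site" (default) or "diagnosis" — what the suppression
        window is keyed on.
    """

    rti_days: int = 14
    onset_cutoff_hours: int = 48
    thresholds: dict[str, float] = field(default_factory=dict)
    tie_break: str = "lowest_rule_id"
    scenario: str = "guideline_plus_expert"
    rti_key: str = "site"

    def __post_init__(self) -> None:
        if self.rti_days < 0:
            raise ValueError("rti_days must be >= 0")
        for d, t in self.thresholds.items():
            if not (0.0 <= t <= 1.0):
                raise ValueError(f"threshold for {d} outside [0, 1]: {t}")
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.rti_key not in ("site", "diagnosis"):
            raise ValueError("rti_key must be 'site' or 'diagnosis'")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "EngineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


# ---------------------------------------------------------------------------
# Condition evaluation and matching
# ---------------------------------------------------------------------------

def evaluate_condition(cond: Condition, case: CaseTuple) -> bool:
    """Evaluate one condition on a case; missing factors are false."""
    fv = case.get(cond.factor_id)
    if fv is None or fv.value is None:
        return False
    v = fv.value
    op, ref = cond.operator, cond.operand
    if op == "eq":
        return v == ref
    if op == "ne":
        return v != ref
    if op == "lt":
        return v < ref
    if op == "le":
        return v <= ref
    if op == "gt":
        return v > ref
    if op == "ge":
        return v >= ref
    if op == "in_range":
        lo, hi = ref
        return lo <= v < hi
    if op == "contains_flag":
        return v == 1
    raise ValueError(f"unknown operator {op!r}")  # pragma: no cover


def match_rules(case: CaseTuple, rules: Sequence[KnowledgeRule]) -> list[FiredRule]:
    """All rules whose full conjunction holds on the case, by rule id."""
    fired = []
    for rule in sorted(rules, key=lambda r: r.rule_id):
        if all(evaluate_condition(c, case) for c in rule.conditions):
            fired.append(
                FiredRule(rule_id=rule.rule_id, diagnosis_code=rule.diagnosis_code,
                          site_code=rule.site_code, probability=rule.probability,
                          patient_id=case.patient_id, episode_id=case.episode_id,
                          as_of_date=case.as_of_date)
            )
    return fired


def select_per_diagnosis(fired: Iterable[FiredRule]) -> list[FiredRule]:
    """Keep the highest-probability firing per diagnosis (ties: lowest id)."""
    best: dict[str, FiredRule] = {}
    for fr in fired:
        cur = best.get(fr.diagnosis_code)
        if cur is None or (fr.probability, _neg_id(fr.rule_id)) > (cur.probability, _neg_id(cur.rule_id)):
            best[fr.diagnosis_code] = fr
    return sorted(best.values(), key=lambda fr: fr.rule_id)


class _neg_id(str):
    """String wrapper whose ordering is reversed (for max-with-min-id ties)."""

    def __lt__(self, other):  # type: ignore[override]
        return str(self) > str(other)

    def __gt__(self, other):  # type: ignore[override]
        return str(self) < str(other)


def classify_onset(case: CaseTuple, config: EngineConfig) -> str:
    """``hospital_acquired`` iff onset lies strictly beyond the cutoff.

    Onset is taken as 00:00 of the firing case's surveillance day; the
    cutoff (default 48 h) is measured from the admission timestamp.
    """
    adm = case.get("admission_datetime")
    if adm is None or adm.value is None:
        raise ValueError(f"case {case.episode_id}/{case.as_of_date}: admission_datetime missing")
    admission = adm.value
    if isinstance(admission, dt.date) and not isinstance(admission, dt.datetime):
        admission = dt.datetime.combine(admission, dt.time())
    onset = dt.datetime.combine(case.as_of_date, dt.time())
    hours = (onset - admission).total_seconds() / 3600.0
    return "hospital_acquired" if hours > config.onset_cutoff_hours else "community_acquired"


def apply_thresholds(warnings: list[WarningResult],
                     thresholds: dict[str, float]) -> list[WarningResult]:
    """Mark warnings with probability strictly below their diagnosis threshold."""
    for w in warnings:
        if w.status != "alerted":
            continue
        if w.probability < thresholds.get(w.diagnosis_code, 0.0):
            w.status = "below_threshold"
    return warnings


def apply_rti(warnings: list[WarningResult], rti_days: int,
              rti_key: str = "site",
              history: Optional[Iterable[tuple[str, str, dt.date]]] = None) -> list[WarningResult]:
    """Suppress same-patient same-site recurrences inside the RTI window.

    ``warnings`` must be sorted by (patient, infection_time); decisions
    are made in time order, and only *alerted* warnings consume the
    window.  ``history`` optionally seeds prior alerts as
    ``(patient_id, key, date)`` triples.
    """
    last_alert: dict[tuple[str, str], dt.date] = {}
    for pid, key, d in history or []:
        k = (pid, key)
        if k not in last_alert or d > last_alert[k]:
            last_alert[k] = d
    for w in warnings:
        if w.status != "alerted":
            continue
        key = (w.patient_id, w.site_code if rti_key == "site" else w.diagnosis_code)
        prev = last_alert.get(key)
        if prev is not None and (w.infection_time - prev).days < rti_days:
            w.status = "suppressed_rti"
        else:
            last_alert[key] = w.infection_time
    return warnings


def run_surveillance(cases: Sequence[CaseTuple], rule_base: RuleBase,
                     config: Optional[EngineConfig] = None,
                     confirmed_labels: Optional[Iterable[GoldLabel]] = None
                     ) -> list[WarningResult]:
    """Full pipeline: match -> select -> onset -> thresholds -> RTI.

    Deterministic for fixed inputs.  When ``confirmed_labels`` is given,
    warnings matching an already-confirmed infection of the same episode
    and site are suppressed regardless of the window (re-alert etiquette:
    physicians who already identified the infection are not alerted
    again); off by default.
    """
    config = config or EngineConfig()
    scoped = filter_by_source(rule_base, config.scenario)
    ordered = sorted(cases, key=lambda c: (c.patient_id, c.as_of_date, c.episode_id))
    warnings: list[WarningResult] = []
    for case in ordered:
        fired = select_per_diagnosis(match_rules(case, scoped.rules))
        if not fired:
            continue
        onset = classify_onset(case, config)
        for fr in fired:
            warnings.append(
                WarningResult(
                    patient_id=fr.patient_id, episode_id=fr.episode_id,
                    infection_time=fr.as_of_date, site_code=fr.site_code,
                    diagnosis_code=fr.diagnosis_code, probability=fr.probability,
                    rule_id=fr.rule_id,
                    status="alerted" if onset == "hospital_acquired" else "community_acquired",
                )
            )
    apply_thresholds(warnings, config.thresholds)
    if confirmed_labels is not None:
        confirmed = {(lb.episode_id, lb.site_code) for lb in confirmed_labels if lb.infected == 1}
        for w in warnings:
            if w.status == "alerted" and (w.episode_id, w.site_code) in confirmed:
                w.status = "suppressed_rti"
    apply_rti(warnings, config.rti_days, config.rti_key)
    return warnings


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

_COLUMNS = ["patient_id", "episode_id", "infection_time", "site_code",
            "diagnosis_code", "probability", "rule_id", "status"]


def write_warnings_csv(warnings: Iterable[WarningResult], path: Union[str, Path]) -> None:
    pd.DataFrame([w.to_dict() for w in warnings], columns=_COLUMNS).to_csv(path, index=False)


def read_warnings_csv(path: Union[str, Path]) -> list[WarningResult]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    return [
        WarningResult(
            patient_id=r.patient_id, episode_id=r.episode_id,
            infection_time=dt.date.fromisoformat(r.infection_time),
            site_code=r.site_code, diagnosis_code=r.diagnosis_code,
            probability=float(r.probability), rule_id=r.rule_id, status=r.status,
        )
        for r in df.itertuples(index=False)
    ]


def write_warnings_jsonl(warnings: Iterable[WarningResult], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for w in warnings:
            fh.write(json.dumps(w.to_dict(), sort_keys=True) + "\n")
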