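"""The 8-tuple case representation and gold-standard labels.

Every inpatient surveillance day is represented as one :class:`CaseTuple`
with eight factor groups:

====  =====================================
DE    demographics (age, gender)
PS    hospitalization status (admission time, hospital day)
PN    progress-note keyword flags
IR    imaging-report keyword flags
VS    vital signs (daily max temperature, defecation frequency)
CL    clinical laboratory (labs + microbiology flags)
OP    operation flags
MO    medical-order flags (catheter, ventilator)
====  =====================================

Numeric/date factors are stored with their native kind; text-derived and
presence factors are binary (0 unsuspected, 1 suspected).  The tuple is
the rule engine's sole input.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional, Union

import pandas as pd

from .factors import FactorRegistry, FactorValue

__all__ = [
    "GROUP_CODES",
    "CaseTuple",
    "ValidationIssue",
    "validate_case",
    "GoldLabel",
    "write_cases_jsonl",
    "read_cases_jsonl",
    "read_gold_labels",
    "write_gold_labels",
]

GROUP_CODES = ("DE", "PS", "PN", "IR", "VS", "CL", "OP", "MO")

_DT_FMT = "%Y-%m-%dT%H:%M:%S"


@dataclass(frozen=True)
class ValidationIssue:
    """One validation finding: which factor (or group) and what is wrong."""

    code: str  # e.g. "missing group", "binary out of domain", "unknown factor"
    group: str = ""
    factor_id: str = ""
    message: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = ".".join(x for x in (self.group, self.factor_id) if x)
        return f"[{self.code}] {loc}: {self.message}" if loc else f"[{self.code}] {self.message}"


@dataclass
class CaseTuple:
    """One patient-episode surveillance day in 8-group factor form."""

    patient_id: str
    episode_id: str
    as_of_date: dt.date
    groups: dict[str, dict[str, FactorValue]] = field(
        default_factory=lambda: {g: {} for g in GROUP_CODES}
    )

    def get(self, factor_id: str) -> Optional[FactorValue]:
        """Look a factor up across all groups; None when absent/missing."""
        for grp in self.groups.values():
            fv = grp.get(factor_id)
            if fv is not None:
                return fv
        return None

    def set(self, group: str, fv: FactorValue) -> None:
        self.groups.setdefault(group, {})[fv.factor_id] = fv

    # -- serialization (JSON-lines friendly) -----------------------------
    def to_dict(self) -> dict:
        def enc(fv: FactorValue):
            v = fv.value
            if isinstance(v, dt.datetime):
                v = v.strftime(_DT_FMT)
            elif isinstance(v, dt.date):
                v = v.isoformat()
            return {"kind": fv.kind, "value": v, "unit": fv.unit}

        return {
            "patient_id": self.patient_id,
            "episode_id": self.episode_id,
            "as_of_date": self.as_of_date.isoformat(),
            "groups": {
                g: {fid: enc(fv) for fid, fv in sorted(self.groups.get(g, {}).items())}
                for g in GROUP_CODES
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CaseTuple":
        groups: dict[str, dict[str, FactorValue]] = {}
        for g, members in data["groups"].items():
            grp = {}
            for fid, enc in members.items():
                v = enc["value"]
                if enc["kind"] == "date" and isinstance(v, str):
                    v = (
                        dt.datetime.strptime(v, _DT_FMT)
                        if "T" in v
                        else dt.date.fromisoformat(v)
                    )
                grp[fid] = FactorValue(factor_id=fid, kind=enc["kind"], value=v, unit=enc.get("unit", ""))
            groups[g] = grp
        return cls(
            patient_id=data["patient_id"],
            episode_id=data["episode_id"],
            as_of_date=dt.date.fromisoformat(data["as_of_date"]),
            groups=groups,
        )


def validate_case(case: CaseTuple, registry: FactorRegistry) -> list[ValidationIssue]:
    """Check a case against the factor registry.

    Returns an empty list iff all 8 groups are present, every factor is
    registered, typed in-domain, placed in its declared group, and no
    factor id appears in more than one group.  Issues are returned, never
    raised; the function is pure and idempotent.
    """
    issues: list[ValidationIssue] = []
    for g in GROUP_CODES:
        if g not in case.groups:
            issues.append(ValidationIssue(code="missing group", group=g, message="group key absent"))
    seen: dict[str, str] = {}
    for g, members in case.groups.items():
        if g not in GROUP_CODES:
            issues.append(ValidationIssue(code="unknown group", group=g, message="not an 8-tuple group"))
            continue
        for fid, fv in members.items():
            if fid in seen:
                issues.append(
                    ValidationIssue(
                        code="duplicate factor", group=g, factor_id=fid,
                        message=f"also present in group {seen[fid]}",
                    )
                )
            seen.setdefault(fid, g)
            spec = registry.get(fid)
            if spec is None:
                issues.append(ValidationIssue(code="unknown factor", group=g, factor_id=fid,
                                              message="not in registry"))
                continue
            if spec.group != g:
                issues.append(
                    ValidationIssue(code="wrong group", group=g, factor_id=fid,
                                    message=f"registered in group {spec.group}")
                )
            if spec.kind != fv.kind:
                issues.append(
                    ValidationIssue(code="kind mismatch", group=g, factor_id=fid,
                                    message=f"registered as {spec.kind}, value is {fv.kind}")
                )
            problem = fv.check()
            if problem:
                code = "binary out of domain" if fv.kind == "binary" else "value out of domain"
                issues.append(ValidationIssue(code=code, group=g, factor_id=fid, message=problem))
    return issues


# ---------------------------------------------------------------------------
# Gold-standard labels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GoldLabel:
    """Confirmed infection status of one episode (reporting-card stand-in)."""

    patient_id: str
    episode_id: str
    infected: int
    diagnosis_code: Optional[str] = None
    site_code: Optional[str] = None
    onset_datetime: Optional[dt.datetime] = None
    report_month: str = ""  # YYYY-MM

    def __post_init__(self) -> None:
        if self.infected not in (0, 1):
            raise ValueError(f"infected must be 0/1, got {self.infected!r}")
        if self.infected == 1 and not (self.diagnosis_code and self.site_code and self.onset_datetime):
            raise ValueError(
                f"episode {self.episode_id}: infected label requires diagnosis, site and onset"
            )


def write_gold_labels(labels: Iterable[GoldLabel], path: Union[str, Path]) -> None:
    rows = [
        {
            "patient_id": lb.patient_id,
            "episode_id": lb.episode_id,
            "infected": lb.infected,
            "diagnosis_code": lb.diagnosis_code or "",
            "site_code": lb.site_code or "",
            "onset_datetime": lb.onset_datetime.strftime(_DT_FMT) if lb.onset_datetime else "",
            "report_month": lb.report_month,
        }
        for lb in labels
    ]
    pd.DataFrame(
        rows,
        columns=["patient_id", "episode_id", "infected", "diagnosis_code",
                 "site_code", "onset_datetime", "report_month"],
    ).to_csv(path, index=False)


def read_gold_labels(path: Union[str, Path]) -> list[GoldLabel]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    labels = []
    for row in df.itertuples(index=False):
        onset = dt.datetime.strptime(row.onset_datetime, _DT_FMT) if row.onset_datetime else None
        labels.append(
            GoldLabel(
                patient_id=row.patient_id,
                episode_id=row.episode_id,
                infected=int(row.infected),
                diagnosis_code=row.diagnosis_code or None,
                site_code=row.site_code or None,
                onset_datetime=onset,
                report_month=row.report_month,
            )
        )
    return labels


# ---------------------------------------------------------------------------
# Case JSON-lines IO
# ---------------------------------------------------------------------------

def write_cases_jsonl(cases: Iterable[CaseTuple], path: Union[str, Path]) -> None:
    with open(path, "w") as fh:
        for case in cases:
            fh.write(json.dumps(case.to_dict(), sort_keys=True) + "\n")


def read_cases_jsonl(path: Union[str, Path]) -> Iterator[CaseTuple]:
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield CaseTuple.from_dict(json.loads(line))
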