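"""Factor extraction: raw multi-source records -> 8-tuple cases.

Three extraction routes feed the case representation:

* direct structured mapping (age, gender, admission time, active orders),
* numeric derivation over time series (highest body temperature of the
  day, latest lab value on or before the day),
* keyword-lexicon flags over free text (progress notes, imaging
  reports), with sentence-level negation cues.

Conventions (documented, and relied on by the tests): day windows are
half-open ``[00:00, 24:00)``; the admission day counts as hospital day 1;
same-day duplicate labs resolve latest-wins; text-derived binary factors
default to 0 while unmeasured numeric factors stay *missing* (absent
from the case), which the engine treats as condition-false.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import yaml

from .cases import GROUP_CODES, CaseTuple
from .factors import FactorRegistry

__all__ = [
    "RawRecordSet",
    "LexiconEntry",
    "KeywordLexicon",
    "load_lexicon",
    "default_lexicon",
    "daily_max_temperature",
    "hospital_days",
    "extract_structured",
    "extract_keywords",
    "build_cases",
]

TEMPERATURE_RANGE = (30.0, 45.0)  # readings outside are implausible, rejected

# Which specimen feeds which binary culture factor (CL group).
SPECIMEN_FACTORS = {
    "pleural_fluid": "pleural_culture_positive",
    "urine": "urine_culture_positive",
    "blood": "blood_culture_positive",
    "sputum": "sputum_culture_positive",
}

# Lab test_id -> (value factor or None, abnormal-flag factor or None).
LAB_FACTORS = {
    "pct": ("pct", None),
    "crp": ("crp", None),
    "blood_wbc": ("blood_wbc", None),
    "urine_wbc": ("urine_wbc", "urine_wbc_abnormal"),
    "urine_bacteria": (None, "urine_bacteria_abnormal"),
    "pleural_wbc": ("pleural_wbc", None),
}

ORDER_FACTORS = {"urinary_catheter": "urinary_catheter", "ventilator": "ventilator"}

_TABLES = ("admissions", "vitals", "labs", "micro", "notes", "operations", "orders")


@dataclass
class RawRecordSet:
    """Delimited-table stand-in for the hospital source systems.

    One DataFrame per source: admissions (HIS), vitals + labs + micro
    (LIS), notes (EMR/PACS reports), operations and orders (HIS).
    """

    admissions: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    micro: pd.DataFrame
    notes: pd.DataFrame
    operations: pd.DataFrame
    orders: pd.DataFrame

    @staticmethod
    def empty() -> "RawRecordSet":
        return RawRecordSet(
            admissions=pd.DataFrame(columns=["patient_id", "episode_id", "admission_datetime",
                                             "discharge_datetime", "age", "gender", "department"]),
            vitals=pd.DataFrame(columns=["episode_id", "datetime", "measure_id", "value"]),
            labs=pd.DataFrame(columns=["episode_id", "datetime", "test_id", "value", "unit", "abnormal_flag"]),
            micro=pd.DataFrame(columns=["episode_id", "datetime", "specimen", "organism", "positive_flag"]),
            notes=pd.DataFrame(columns=["episode_id", "datetime", "note_type", "text"]),
            operations=pd.DataFrame(columns=["episode_id", "datetime", "procedure_name"]),
            orders=pd.DataFrame(columns=["episode_id", "start", "end", "order_type"]),
        )

    def validate(self) -> list[str]:
        """Structural issues: orphan episodes, timestamps outside the stay.

        Timestamps must lie within [admission - 1 day, discharge + 1 day].
        Issues are returned as human-readable strings with row references.
        """
        issues: list[str] = []
        adm = self.admissions
        known = set(adm["episode_id"])
        bounds = {
            r.episode_id: (r.admission_datetime - pd.Timedelta(days=1),
                           r.discharge_datetime + pd.Timedelta(days=1))
            for r in adm.itertuples(index=False)
        }
        for name, time_cols in (("vitals", ["datetime"]), ("labs", ["datetime"]),
                                ("micro", ["datetime"]), ("notes", ["datetime"]),
                                ("operations", ["datetime"]), ("orders", ["start", "end"])):
            df = getattr(self, name)
            for i, row in enumerate(df.itertuples(index=False)):
                if row.episode_id not in known:
                    issues.append(f"{name} row {i}: unknown episode_id {row.episode_id!r}")
                    continue
                lo, hi = bounds[row.episode_id]
                for col in time_cols:
                    ts = getattr(row, col)
                    if pd.isna(ts):
                        issues.append(f"{name} row {i}: unparseable {col}")
                    elif not (lo <= ts <= hi):
                        issues.append(f"{name} row {i}: {col} {ts} outside stay of {row.episode_id}")
        return issues

    # -- CSV round trip --------------------------------------------------
    def to_dir(self, path: Union[str, Path]) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in _TABLES:
            getattr(self, name).to_csv(path / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, path: Union[str, Path]) -> "RawRecordSet":
        path = Path(path)
        frames = {}
        datetime_cols = {
            "admissions": ["admission_datetime", "discharge_datetime"],
            "vitals": ["datetime"], "labs": ["datetime"], "micro": ["datetime"],
            "notes": ["datetime"], "operations": ["datetime"], "orders": ["start", "end"],
        }
        for name in _TABLES:
            df = pd.read_csv(path / f"{name}.csv", dtype={"episode_id": str, "patient_id": str})
            for col in datetime_cols[name]:
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col], errors="coerce")
            frames[name] = df
        return cls(**frames)


# ---------------------------------------------------------------------------
# Keyword lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LexiconEntry:
    factor_id: str
    note_type: str  # "progress" | "imaging"
    keywords: tuple[str, ...]
    negation_cues: tuple[str, ...]
    case_sensitive: bool = False

    def __post_init__(self) -> None:
        if not self.keywords:
            raise ValueError(f"lexicon entry {self.factor_id!r}: keywords must be non-empty")


@dataclass
class KeywordLexicon:
    entries: tuple[LexiconEntry, ...]

    def validate(self, registry: FactorRegistry) -> list[str]:
        issues = []
        for e in self.entries:
            spec = registry.get(e.factor_id)
            if spec is None:
                issues.append(f"lexicon: unknown factor {e.factor_id!r}")
            elif spec.kind != "binary":
                issues.append(f"lexicon: factor {e.factor_id!r} must be binary, is {spec.kind}")
        return issues


def _lexicon_from_dict(data: dict) -> KeywordLexicon:
    default_cues = tuple(data.get("negation_cues_default", []))
    entries = tuple(
        LexiconEntry(
            factor_id=str(e["factor_id"]),
            note_type=str(e["note_type"]),
            keywords=tuple(str(k) for k in e["keywords"]),
            negation_cues=tuple(str(c) for c in e.get("negation_cues", default_cues)),
            case_sensitive=bool(e.get("case_sensitive", False)),
        )
        for e in data["entries"]
    )
    return KeywordLexicon(entries=entries)


def load_lexicon(path: Union[str, Path]) -> KeywordLexicon:
    return _lexicon_from_dict(yaml.safe_load(Path(path).read_text()))


def default_lexicon() -> KeywordLexicon:
    ref = resources.files("haisurv.data") / "lexicon_default.yaml"
    return _lexicon_from_dict(yaml.safe_load(ref.read_text()))


_WS = re.compile(r"\s+")
_SENT_SPLIT = re.compile(r"[.!?;\n]+")


def _normalize(text: str, case_sensitive: bool) -> str:
    text = _WS.sub(" ", text)
    return text if case_sensitive else text.casefold()


def _text_hits(text: str, entry: LexiconEntry) -> bool:
    """True iff any keyword occurs in a sentence free of negation cues."""
    for sentence in _SENT_SPLIT.split(text):
        norm = _normalize(sentence, entry.case_sensitive)
        kws = entry.keywords if entry.case_sensitive else tuple(k.casefold() for k in entry.keywords)
        cues = entry.negation_cues if entry.case_sensitive else tuple(c.casefold() for c in entry.negation_cues)
        if any(k in norm for k in kws) and not any(c in norm for c in cues):
            return True
    return False


# ---------------------------------------------------------------------------
# Scalar derivations
# ---------------------------------------------------------------------------

def daily_max_temperature(series: pd.DataFrame, day: dt.date) -> Optional[float]:
    """Highest plausible temperature reading within ``[day 00:00, day+1 00:00)``.

    ``series`` needs columns ``datetime`` and ``value``.  Readings outside
    the plausible range 30-45 degC are rejected; an empty day yields None.
    """
    if series.empty:
        return None
    start = pd.Timestamp(day)
    end = start + pd.Timedelta(days=1)
    vals = series.loc[
        (series["datetime"] >= start)
        & (series["datetime"] < end)
        & (series["value"] >= TEMPERATURE_RANGE[0])
        & (series["value"] <= TEMPERATURE_RANGE[1]),
        "value",
    ]
    return None if vals.empty else float(vals.max())


def hospital_days(admission: dt.datetime, as_of: dt.date) -> int:
    """Calendar hospital day: admission day is day 1, day boundaries at midnight.

    A patient admitted at 23:50 is on hospital day 2 ten minutes later.
    """
    adm_date = admission.date() if isinstance(admission, dt.datetime) else admission
    delta = (as_of - adm_date).days
    if delta < 0:
        raise ValueError(f"as_of {as_of} precedes admission date {adm_date}")
    return delta + 1


# ---------------------------------------------------------------------------
# Per-episode index (built once, queried per day)
# ---------------------------------------------------------------------------

class _EpisodeIndex:
    def __init__(self, records: RawRecordSet, lexicon: Optional[KeywordLexicon]):
        self.admissions = {r.episode_id: r for r in records.admissions.itertuples(index=False)}
        self.vitals = dict(tuple(records.vitals.groupby("episode_id", sort=False))) if not records.vitals.empty else {}
        self.labs = dict(tuple(records.labs.groupby("episode_id", sort=False))) if not records.labs.empty else {}
        self.micro = dict(tuple(records.micro.groupby("episode_id", sort=False))) if not records.micro.empty else {}
        self.operations = dict(tuple(records.operations.groupby("episode_id", sort=False))) if not records.operations.empty else {}
        self.orders = dict(tuple(records.orders.groupby("episode_id", sort=False))) if not records.orders.empty else {}
        # first date each keyword flag turns on, per episode
        self.first_hit: dict[str, dict[str, dt.date]] = {}
        self.day_hits: dict[str, dict[tuple[str, dt.date], bool]] = {}
        if lexicon is not None and not records.notes.empty:
            for eid, notes in records.notes.groupby("episode_id", sort=False):
                hits: dict[str, dt.date] = {}
                per_day: dict[tuple[str, dt.date], bool] = {}
                for entry in lexicon.entries:
                    sub = notes[notes["note_type"] == entry.note_type]
                    for row in sub.itertuples(index=False):
                        if pd.isna(row.datetime) or not isinstance(row.text, str):
                            continue
                        if _text_hits(row.text, entry):
                            d = row.datetime.date()
                            per_day[(entry.factor_id, d)] = True
                            if entry.factor_id not in hits or d < hits[entry.factor_id]:
                                hits[entry.factor_id] = d
                self.first_hit[eid] = hits
                self.day_hits[eid] = per_day


# ---------------------------------------------------------------------------
# Extraction operations
# ---------------------------------------------------------------------------

def _structured_groups(idx: _EpisodeIndex, registry: FactorRegistry,
                       episode_id: str, day: dt.date) -> dict[str, dict]:
    """Structured + derived factors for one episode on one day."""
    adm = idx.admissions[episode_id]
    groups: dict[str, dict] = {g: {} for g in GROUP_CODES}

    def put(group: str, fid: str, value) -> None:
        if fid in registry:
            groups[group][fid] = registry.make(fid, value)

    put("DE", "age", int(adm.age))
    put("DE", "gender", int(adm.gender))
    admission = adm.admission_datetime.to_pydatetime()
    put("PS", "admission_datetime", admission)
    put("PS", "hospital_days", hospital_days(admission, day))

    vit = idx.vitals.get(episode_id)
    if vit is not None:
        temp = daily_max_temperature(vit[vit["measure_id"] == "body_temperature"], day)
        if temp is not None:
            put("VS", "body_temperature_max", temp)
        start, end = pd.Timestamp(day), pd.Timestamp(day) + pd.Timedelta(days=1)
        defec = vit[(vit["measure_id"] == "defecation_frequency")
                    & (vit["datetime"] >= start) & (vit["datetime"] < end)]
        if not defec.empty:
            put("VS", "defecation_frequency", int(defec.sort_values("datetime").iloc[-1]["value"]))

    cutoff = pd.Timestamp(day) + pd.Timedelta(days=1)  # on-or-before day, half-open
    labs = idx.labs.get(episode_id)
    has_pct = 0
    if labs is not None:
        past = labs[labs["datetime"] < cutoff]
        for test_id, sub in past.groupby("test_id", sort=False):
            latest = sub.sort_values("datetime", kind="stable").iloc[-1]  # latest-wins
            value_fid, flag_fid = LAB_FACTORS.get(test_id, (None, None))
            if value_fid:
                spec = registry.get(value_fid)
                if spec is not None:
                    v = float(latest["value"])
                    put("CL", value_fid, int(v) if spec.kind == "integer" else v)
            if flag_fid:
                put("CL", flag_fid, int(latest["abnormal_flag"]))
            if test_id == "pct":
                has_pct = 1
    put("CL", "has_pct_lab", has_pct)

    micro = idx.micro.get(episode_id)
    positives: dict[str, int] = {fid: 0 for fid in SPECIMEN_FACTORS.values()}
    if micro is not None:
        past = micro[micro["datetime"] < cutoff]
        for row in past.itertuples(index=False):
            fid = SPECIMEN_FACTORS.get(row.specimen)
            if fid and int(row.positive_flag) == 1:
                positives[fid] = 1
    for fid, v in positives.items():
        put("CL", fid, v)

    ops = idx.operations.get(episode_id)
    had_op = 0
    if ops is not None and not ops[ops["datetime"] < cutoff].empty:
        had_op = 1
    put("OP", "recent_operation", had_op)

    orders = idx.orders.get(episode_id)
    active = {fid: 0 for fid in ORDER_FACTORS.values()}
    if orders is not None:
        day_ts = pd.Timestamp(day)
        for row in orders.itertuples(index=False):
            fid = ORDER_FACTORS.get(row.order_type)
            # an order is active on `day` when its interval covers any part of it
            if fid and row.start < cutoff and row.end >= day_ts:
                active[fid] = 1
    for fid, v in active.items():
        put("MO", fid, v)
    return groups


def extract_structured(records: RawRecordSet, day: dt.date,
                       registry: FactorRegistry) -> dict[str, dict[str, dict]]:
    """Structured/derived factor maps for every episode in-hospital on ``day``.

    Returns ``{episode_id: {group: {factor_id: FactorValue}}}`` for
    episodes whose stay covers ``day``.
    """
    idx = _EpisodeIndex(records, lexicon=None)
    out = {}
    for eid, adm in idx.admissions.items():
        if adm.admission_datetime.date() <= day <= adm.discharge_datetime.date():
            out[eid] = _structured_groups(idx, registry, eid, day)
    return out


def extract_keywords(notes: pd.DataFrame, lexicon: KeywordLexicon, day: dt.date,
                     scope: str = "to_date") -> dict[str, int]:
    """Binary text-derived factors for one episode's notes.

    A factor is 1 iff some note of the matching type, dated on or before
    ``day`` (``scope="to_date"``, default) or exactly on ``day``
    (``scope="same_day"``), contains a keyword in a sentence free of
    negation cues.  Never missing: absent evidence yields 0.
    """
    flags: dict[str, int] = {}
    for entry in lexicon.entries:
        flags[entry.factor_id] = 0
        sub = notes[notes["note_type"] == entry.note_type]
        for row in sub.itertuples(index=False):
            d = row.datetime.date()
            in_scope = (d <= day) if scope == "to_date" else (d == day)
            if in_scope and isinstance(row.text, str) and _text_hits(row.text, entry):
                flags[entry.factor_id] = 1
                break
    return flags


def build_cases(records: RawRecordSet, lexicon: KeywordLexicon,
                registry: FactorRegistry,
                day_range: Optional[tuple[dt.date, dt.date]] = None,
                keyword_scope: str = "to_date") -> list[CaseTuple]:
    """One :class:`CaseTuple` per episode per in-hospital day in ``day_range``.

    ``day_range`` is inclusive; None spans all admissions.  Output is
    sorted by (patient_id, episode_id, as_of_date) and deterministic for
    identical inputs.
    """
    if records.admissions.empty:
        return []
    idx = _EpisodeIndex(records, lexicon)
    if day_range is None:
        day_range = (records.admissions["admission_datetime"].min().date(),
                     records.admissions["discharge_datetime"].max().date())
    lo, hi = day_range
    cases: list[CaseTuple] = []
    order = sorted(idx.admissions, key=lambda e: (idx.admissions[e].patient_id, e))
    for eid in order:
        adm = idx.admissions[eid]
        day = max(adm.admission_datetime.date(), lo)
        last = min(adm.discharge_datetime.date(), hi)
        while day <= last:
            groups = _structured_groups(idx, registry, eid, day)
            if keyword_scope == "to_date":
                hits = idx.first_hit.get(eid, {})
                flag_on = {e.factor_id: (e.factor_id in hits and hits[e.factor_id] <= day)
                           for e in lexicon.entries}
            else:
                per_day = idx.day_hits.get(eid, {})
                flag_on = {e.factor_id: per_day.get((e.factor_id, day), False)
                           for e in lexicon.entries}
            for entry in lexicon.entries:
                group = "PN" if entry.note_type == "progress" else "IR"
                groups[group][entry.factor_id] = registry.make(
                    entry.factor_id, 1 if flag_on[entry.factor_id] else 0)
            cases.append(CaseTuple(patient_id=adm.patient_id, episode_id=eid,
                                   as_of_date=day, groups=groups))
            day += dt.timedelta(days=1)
    return cases
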