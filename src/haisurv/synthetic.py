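"""Synthetic inpatient cohort generator with rule-consistent infections.

Real HAI surveillance data are confidential, so every pipeline stage is
exercised on generated multi-source record sets.  The generator emulates
the shape of a provincial-hospital cohort: a low HAI prevalence (3% by
default), a long-tail diagnosis mixture headed by lower respiratory
tract infection, and admission records spanning a calendar window.

Each infected episode is constructed to *satisfy one concrete knowledge
rule*: an onset day is chosen strictly beyond the 48-hour
community-acquired cutoff (and beyond any hospital-days gate the rule
carries), and for every rule condition a record-level realization is
appended — a temperature reading inside the rule's range, a lab row
exceeding its cutoff, a culture row, a note containing a lexicon keyword
for the required flag.  With factor dropout ``q = 0`` the engine is
therefore guaranteed to recover every injected infection (end-to-end
sensitivity 1); raising ``q`` removes each supporting record with that
probability and degrades sensitivity accordingly.  Uninfected episodes
carry physiologic baselines (temperature 36-37.2 degC, normal labs,
benign notes), optionally contaminated with lexicon keywords at the
note-noise rate.

All randomness flows through one seeded generator; identical specs give
byte-identical outputs.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .cases import GoldLabel
from .catalog import InfectionCatalog, default_catalog
from .extraction import KeywordLexicon, RawRecordSet, default_lexicon
from .rules import Condition, KnowledgeRule, RuleBase, default_rule_base

__all__ = ["CohortSpec", "generate_cohort", "inject_infection"]

# Long-tail default over the diagnoses that have packaged exemplar rules,
# LRI heaviest (the most frequent HAI), then UTI, then the rarer PCI.
DEFAULT_MIXTURE = {"LRI": 0.60, "UTI": 0.25, "PCI": 0.15}

_DEPARTMENTS = ("internal medicine", "surgery", "icu", "neurology", "oncology")
_BENIGN_PROGRESS = (
    "Patient resting comfortably, vital signs stable.",
    "Tolerating diet well, ambulating in hallway.",
    "Wound dressing changed, site clean and dry.",
    "Patient slept well, pain controlled.",
)
_BENIGN_IMAGING = (
    "Heart size within normal limits. Clear lung fields.",
    "Unremarkable study. Normal bowel gas pattern.",
)

_SPECIMEN_OF = {
    "pleural_culture_positive": ("pleural_fluid", "Staphylococcus aureus"),
    "urine_culture_positive": ("urine", "Escherichia coli"),
    "blood_culture_positive": ("blood", "Staphylococcus epidermidis"),
    "sputum_culture_positive": ("sputum", "Klebsiella pneumoniae"),
}
_LAB_OF = {"pct": "pct", "crp": "crp", "blood_wbc": "blood_wbc",
           "urine_wbc": "urine_wbc", "pleural_wbc": "pleural_wbc"}


@dataclass
class CohortSpec:
    """Study conditions of one generated cohort.

    Defaults are the desk-scale conditions the test-suite runs under:
    500 episodes over a quarter, 3% HAI prevalence, mean length of stay
    7 days, no factor dropout, 2% note noise.
    """

    seed: int
    n_patients: int = 500
    start: dt.date = dt.date(2020, 1, 1)
    end: dt.date = dt.date(2020, 3, 31)
    prevalence: float = 0.03
    mixture: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    mean_los: float = 7.0
    dropout_q: float = 0.0
    note_noise: float = 0.02

    def __post_init__(self) -> None:
        for name in ("prevalence", "dropout_q", "note_noise"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.end < self.start:
            raise ValueError("end date precedes start date")
        total = sum(self.mixture.values())
        if self.mixture and abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        if any(w < 0 for w in self.mixture.values()):
            raise ValueError("mixture weights must be non-negative")


class _EpisodeDraft:
    """Mutable row buffers for one episode while conditions are realized."""

    def __init__(self) -> None:
        self.admission: dict = {}
        self.vitals: list[dict] = []
        self.labs: list[dict] = []
        self.micro: list[dict] = []
        self.notes: list[dict] = []
        self.operations: list[dict] = []
        self.orders: list[dict] = []


def _min_onset_day(rule: KnowledgeRule) -> int:
    """Earliest hospital day satisfying the 48-h cutoff and any day gates."""
    day = 4  # midnight of day 4 is > 48 h after any admission clock time
    for c in rule.conditions:
        if c.factor_id == "hospital_days":
            if c.operator == "ge":
                day = max(day, int(c.operand))
            elif c.operator == "gt":
                day = max(day, int(c.operand) + 1)
            elif c.operator == "in_range":
                day = max(day, int(c.operand[0]))
    return day


def _numeric_satisfying(cond: Condition) -> float:
    op, ref = cond.operator, cond.operand
    if op == "in_range":
        lo, hi = ref
        return round(lo + 0.3 * (hi - lo), 1)
    if op in ("gt", "ge"):
        return float(ref) * 1.5 if ref > 0 else float(ref) + 5.0
    if op in ("lt", "le"):
        return float(ref) / 2.0 if ref > 0 else float(ref) - 5.0
    if op == "eq":
        return float(ref)
    raise ValueError(f"no numeric realization for operator {op!r}")


def inject_infection(draft: _EpisodeDraft, diagnosis_code: str, rule: KnowledgeRule,
                     onset: dt.datetime, lexicon: KeywordLexicon,
                     rng: np.random.Generator, dropout_q: float = 0.0) -> None:
    """Edit an episode draft so every condition of ``rule`` is satisfied
    by factor extraction on the onset date.

    Each record-producing factor is independently omitted with
    probability ``dropout_q`` (structural factors — age, the onset-day
    placement satisfying hospital-day gates — are not droppable).
    Raises for conditions with no record-level realization.
    """
    if rule.diagnosis_code != diagnosis_code:
        raise ValueError(f"rule {rule.rule_id} targets {rule.diagnosis_code}, not {diagnosis_code}")
    admission = draft.admission["admission_datetime"]
    if (onset - admission).total_seconds() <= 48 * 3600:
        raise ValueError(f"onset {onset} is within 48 h of admission {admission}")
    if onset > draft.admission["discharge_datetime"]:
        raise ValueError("onset after discharge")
    eid = draft.admission["episode_id"]
    lex_by_factor = {e.factor_id: e for e in lexicon.entries}

    def kept(factor_id: str) -> bool:
        # one rng draw per record-producing factor, in condition order;
        # always drawn so cohorts differing only in q share their population
        return rng.random() >= dropout_q

    # group lab-value and lab-flag conditions per test so one row serves both
    lab_rows: dict[str, dict] = {}

    for cond in rule.conditions:
        fid = cond.factor_id
        if fid == "hospital_days":
            continue  # structural: guaranteed by onset-day choice
        if fid == "age":
            ref = int(cond.operand if not isinstance(cond.operand, tuple) else cond.operand[0])
            if cond.operator in ("ge", "gt"):
                draft.admission["age"] = ref + int(rng.integers(1, 15))
            elif cond.operator in ("le", "lt"):
                draft.admission["age"] = max(0, ref - int(rng.integers(1, 15)))
            else:
                draft.admission["age"] = int(_numeric_satisfying(cond))
            continue
        if fid == "body_temperature_max":
            if kept(fid):
                draft.vitals.append({"episode_id": eid,
                                     "datetime": onset.replace(hour=12, minute=0),
                                     "measure_id": "body_temperature",
                                     "value": _numeric_satisfying(cond)})
            continue
        if fid == "defecation_frequency":
            if kept(fid):
                draft.vitals.append({"episode_id": eid,
                                     "datetime": onset.replace(hour=18, minute=0),
                                     "measure_id": "defecation_frequency",
                                     "value": _numeric_satisfying(cond)})
            continue
        if fid in _LAB_OF:
            row = lab_rows.setdefault(fid, {"episode_id": eid, "datetime": onset,
                                            "test_id": _LAB_OF[fid], "value": 0.0,
                                            "unit": "", "abnormal_flag": 1})
            row["value"] = _numeric_satisfying(cond)
            continue
        if fid == "has_pct_lab":
            lab_rows.setdefault("pct", {"episode_id": eid, "datetime": onset,
                                        "test_id": "pct", "value": 2.5,
                                        "unit": "ng/mL", "abnormal_flag": 1})
            continue
        if fid == "urine_wbc_abnormal":
            row = lab_rows.setdefault("urine_wbc", {"episode_id": eid, "datetime": onset,
                                                    "test_id": "urine_wbc", "value": 30.0,
                                                    "unit": "1e6/L", "abnormal_flag": 1})
            row["abnormal_flag"] = 1
            continue
        if fid == "urine_bacteria_abnormal":
            lab_rows.setdefault("urine_bacteria", {"episode_id": eid, "datetime": onset,
                                                   "test_id": "urine_bacteria", "value": 1.0,
                                                   "unit": "", "abnormal_flag": 1})
            continue
        if fid in _SPECIMEN_OF:
            if kept(fid):
                specimen, organism = _SPECIMEN_OF[fid]
                draft.micro.append({"episode_id": eid, "datetime": onset,
                                    "specimen": specimen, "organism": organism,
                                    "positive_flag": 1})
            continue
        if fid in lex_by_factor:
            entry = lex_by_factor[fid]
            kw = entry.keywords[int(rng.integers(len(entry.keywords)))]
            if kept(fid):
                text = (f"Patient reports {kw} today."
                        if entry.note_type == "progress"
                        else f"Findings: {kw} is seen.")
                draft.notes.append({"episode_id": eid, "datetime": onset,
                                    "note_type": entry.note_type, "text": text})
            continue
        if fid == "urinary_catheter" or fid == "ventilator":
            if kept(fid):
                draft.orders.append({"episode_id": eid,
                                     "start": admission,
                                     "end": draft.admission["discharge_datetime"],
                                     "order_type": fid})
            continue
        if fid == "recent_operation":
            if kept(fid):
                draft.operations.append({"episode_id": eid,
                                         "datetime": admission + dt.timedelta(days=1),
                                         "procedure_name": "exploratory procedure"})
            continue
        raise ValueError(f"no record-level realization defined for factor {fid!r}")

    for fid, row in lab_rows.items():
        if kept(fid):
            draft.labs.append(row)


def generate_cohort(spec: CohortSpec,
                    rule_base: Optional[RuleBase] = None,
                    catalog: Optional[InfectionCatalog] = None,
                    lexicon: Optional[KeywordLexicon] = None
                    ) -> tuple[RawRecordSet, list[GoldLabel]]:
    """Generate a raw record set plus complete gold labels.

    Deterministic given ``spec.seed``.  Raises when the mixture assigns
    positive weight to a diagnosis with no rule in ``rule_base``.
    """
    rule_base = rule_base or default_rule_base()
    catalog = catalog or default_catalog()
    lexicon = lexicon or default_lexicon()
    for d, w in spec.mixture.items():
        if w > 0 and not rule_base.rules_for(d):
            raise ValueError(f"mixture requests diagnosis {d!r} but the rule base has no rule for it")

    rng = np.random.default_rng(spec.seed)
    diagnoses = sorted(d for d, w in spec.mixture.items() if w > 0)
    weights = np.array([spec.mixture[d] for d in diagnoses])
    weights = weights / weights.sum() if len(weights) else weights

    drafts: list[_EpisodeDraft] = []
    labels: list[GoldLabel] = []
    span_days = (spec.end - spec.start).days + 1

    for i in range(spec.n_patients):
        pid, eid = f"P{i + 1:05d}", f"E{i + 1:05d}"
        adm_date = spec.start + dt.timedelta(days=int(rng.integers(0, span_days)))
        admission = dt.datetime.combine(
            adm_date, dt.time(int(rng.integers(7, 13)), int(rng.integers(0, 60))))
        age = int(rng.integers(18, 91))
        gender = int(rng.integers(0, 2))
        department = _DEPARTMENTS[int(rng.integers(len(_DEPARTMENTS)))]
        los = 1 + int(rng.poisson(max(spec.mean_los - 1.0, 0.0)))
        infected = bool(rng.random() < spec.prevalence) and len(diagnoses) > 0

        diagnosis = rule = None
        onset_day = 0
        if infected:
            diagnosis = diagnoses[int(rng.choice(len(diagnoses), p=weights))]
            candidates = rule_base.rules_for(diagnosis)
            rule = candidates[int(rng.integers(len(candidates)))]
            onset_day = _min_onset_day(rule) + int(rng.integers(0, 3))
            los = max(los, onset_day + 1)

        discharge = dt.datetime.combine(adm_date + dt.timedelta(days=los - 1), dt.time(16, 0))
        draft = _EpisodeDraft()
        draft.admission = {
            "patient_id": pid, "episode_id": eid, "admission_datetime": admission,
            "discharge_datetime": discharge, "age": age, "gender": gender,
            "department": department,
        }

        # physiologic baselines: two temperature readings per stay day
        for d in range(los):
            day = adm_date + dt.timedelta(days=d)
            for hour in (8, 16):
                temp = float(np.clip(rng.normal(36.6, 0.2), 36.0, 37.2))
                draft.vitals.append({"episode_id": eid,
                                     "datetime": dt.datetime.combine(day, dt.time(hour, 0)),
                                     "measure_id": "body_temperature",
                                     "value": round(temp, 1)})
        draft.labs.append({"episode_id": eid, "datetime": admission + dt.timedelta(hours=2),
                           "test_id": "blood_wbc",
                           "value": round(float(np.clip(rng.normal(6.5, 1.5), 4.0, 10.0)), 1),
                           "unit": "1e9/L", "abnormal_flag": 0})
        draft.notes.append({"episode_id": eid, "datetime": admission + dt.timedelta(hours=4),
                            "note_type": "progress",
                            "text": _BENIGN_PROGRESS[int(rng.integers(len(_BENIGN_PROGRESS)))]})

        if infected:
            onset = dt.datetime.combine(adm_date + dt.timedelta(days=onset_day - 1),
                                        dt.time(10, 0))
            inject_infection(draft, diagnosis, rule, onset, lexicon, rng,
                             dropout_q=spec.dropout_q)
            labels.append(GoldLabel(
                patient_id=pid, episode_id=eid, infected=1,
                diagnosis_code=diagnosis, site_code=catalog.site_of(diagnosis),
                onset_datetime=onset, report_month=onset.strftime("%Y-%m")))
        else:
            if rng.random() < spec.note_noise and lexicon.entries:
                entry = lexicon.entries[int(rng.integers(len(lexicon.entries)))]
                kw = entry.keywords[int(rng.integers(len(entry.keywords)))]
                noise_day = adm_date + dt.timedelta(days=int(rng.integers(0, los)))
                draft.notes.append({
                    "episode_id": eid,
                    "datetime": dt.datetime.combine(noise_day, dt.time(11, 0)),
                    "note_type": entry.note_type,
                    "text": f"Documentation mentions {kw} in passing.",
                })
            labels.append(GoldLabel(patient_id=pid, episode_id=eid, infected=0,
                                    report_month=adm_date.strftime("%Y-%m")))
        drafts.append(draft)

    def frame(rows: list[dict], columns: list[str]) -> pd.DataFrame:
        return pd.DataFrame(rows, columns=columns)

    records = RawRecordSet(
        admissions=frame([d.admission for d in drafts],
                         ["patient_id", "episode_id", "admission_datetime",
                          "discharge_datetime", "age", "gender", "department"]),
        vitals=frame([r for d in drafts for r in d.vitals],
                     ["episode_id", "datetime", "measure_id", "value"]),
        labs=frame([r for d in drafts for r in d.labs],
                   ["episode_id", "datetime", "test_id", "value", "unit", "abnormal_flag"]),
        micro=frame([r for d in drafts for r in d.micro],
                    ["episode_id", "datetime", "specimen", "organism", "positive_flag"]),
        notes=frame([r for d in drafts for r in d.notes],
                    ["episode_id", "datetime", "note_type", "text"]),
        operations=frame([r for d in drafts for r in d.operations],
                         ["episode_id", "datetime", "procedure_name"]),
        orders=frame([r for d in drafts for r in d.orders],
                     ["episode_id", "start", "end", "order_type"]),
    )
    return records, labels
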