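"""Episode-level scoring of surveillance warnings against gold labels.

Metrics are the standard screening triple

    ACC = (TP + TN) / (P + N)
    SEN = TP / (TP + FN)
    SPE = TN / (TN + FP)

computed per stratum (overall, month, diagnosis, site) and per rule-base
scenario.  The scoring unit is the inpatient episode; a gold-infected
episode counts as TP when at least one *alerted* warning matches it at
the configured granularity (site by default — matching on diagnosis or
on any alert is available).  Undefined metrics (zero denominator) are
reported as missing, never as 0.

Per-diagnosis and per-site strata score *all* episodes for presence or
absence of that stratum's label/warning, so their TN pools are large and
their specificity correspondingly high — the expected behaviour when
true positives are a small fraction of the cohort.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd

from .cases import GoldLabel
from .catalog import InfectionCatalog
from .engine import WarningResult

__all__ = [
    "ConfusionCounts",
    "metrics",
    "score_episode_level",
    "EvalRow",
    "EvalReport",
    "stratified_report",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def p(self) -> int:
        return self.tp + self.fn

    @property
    def n(self) -> int:
        return self.tn + self.fp

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)


def metrics(counts: ConfusionCounts) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(ACC, SEN, SPE); each None when its denominator is zero."""
    acc = (counts.tp + counts.tn) / (counts.p + counts.n) if counts.p + counts.n else None
    sen = counts.tp / counts.p if counts.p else None
    spe = counts.tn / counts.n if counts.n else None
    return acc, sen, spe


def _alert_matches(warning: WarningResult, gold: GoldLabel, granularity: str) -> bool:
    if granularity == "any":
        return True
    if granularity == "site":
        return warning.site_code == gold.site_code
    if granularity == "diagnosis":
        return warning.diagnosis_code == gold.diagnosis_code
    raise ValueError(f"unknown match granularity {granularity!r}")


def score_episode_level(warnings: Sequence[WarningResult], gold: Sequence[GoldLabel],
                        catalog: Optional[InfectionCatalog] = None,
                        match: str = "site") -> ConfusionCounts:
    """Confusion counts over episodes.

    TP: gold-infected episode with >= 1 alerted warning matching at the
    ``match`` granularity; FN: gold-infected without one; FP:
    gold-uninfected episode with any alerted warning; TN: gold-uninfected
    without.  Warnings citing episodes absent from the gold set are an
    error (the gold set must cover the scored cohort).
    """
    by_episode: dict[str, list[WarningResult]] = {}
    gold_ids = {lb.episode_id for lb in gold}
    unknown = sorted({w.episode_id for w in warnings} - gold_ids)
    if unknown:
        raise ValueError(f"warnings reference episodes absent from gold labels: {unknown}")
    for w in warnings:
        if w.status == "alerted":
            by_episode.setdefault(w.episode_id, []).append(w)
    tp = fp = fn = tn = 0
    for lb in gold:
        alerts = by_episode.get(lb.episode_id, [])
        if lb.infected == 1:
            if any(_alert_matches(w, lb, match) for w in alerts):
                tp += 1
            else:
                fn += 1
        else:
            if alerts:
                fp += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass(frozen=True)
class EvalRow:
    stratum_type: str  # overall | month | diagnosis | site
    stratum: str
    scenario: str
    counts: ConfusionCounts
    acc: Optional[float]
    sen: Optional[float]
    spe: Optional[float]


@dataclass
class EvalReport:
    rows: list[EvalRow]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "stratum_type": r.stratum_type, "stratum": r.stratum,
                    "scenario": r.scenario, "TP": r.counts.tp, "FP": r.counts.fp,
                    "FN": r.counts.fn, "TN": r.counts.tn,
                    "ACC": r.acc, "SEN": r.sen, "SPE": r.spe,
                }
                for r in self.rows
            ],
            columns=["stratum_type", "stratum", "scenario", "TP", "FP", "FN", "TN",
                     "ACC", "SEN", "SPE"],
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_dataframe().to_json(orient="records", indent=2))

    def lookup(self, stratum_type: str, stratum: str, scenario: str) -> EvalRow:
        for r in self.rows:
            if (r.stratum_type, r.stratum, r.scenario) == (stratum_type, stratum, scenario):
                return r
        raise KeyError((stratum_type, stratum, scenario))

    def average(self, stratum_type: str, scenario: str, metric: str) -> Optional[float]:
        """Unweighted mean of a metric over strata where it is defined."""
        vals = [getattr(r, metric) for r in self.rows
                if r.stratum_type == stratum_type and r.scenario == scenario
                and getattr(r, metric) is not None]
        return sum(vals) / len(vals) if vals else None


def _row(stratum_type: str, stratum: str, scenario: str, counts: ConfusionCounts) -> EvalRow:
    acc, sen, spe = metrics(counts)
    return EvalRow(stratum_type, stratum, scenario, counts, acc, sen, spe)


def _binary_counts(gold: Sequence[GoldLabel], positive: set[str],
                   predicted: set[str]) -> ConfusionCounts:
    tp = fp = fn = tn = 0
    for lb in gold:
        is_pos = lb.episode_id in positive
        is_pred = lb.episode_id in predicted
        if is_pos and is_pred:
            tp += 1
        elif is_pos:
            fn += 1
        elif is_pred:
            fp += 1
        else:
            tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def stratified_report(warnings_by_scenario: Mapping[str, Sequence[WarningResult]],
                      gold: Sequence[GoldLabel], catalog: InfectionCatalog,
                      by: Iterable[str] = ("month", "diagnosis", "site"),
                      match: str = "site",
                      months: Optional[Sequence[str]] = None) -> EvalReport:
    """Confusion counts and ACC/SEN/SPE per stratum and scenario.

    Month strata partition episodes by gold ``report_month`` (counts are
    additive across months).  Diagnosis/site strata score every episode
    for that one diagnosis/site: positive iff the gold label carries it,
    predicted iff an alerted warning carries it; true negatives are the
    (many) episodes with neither.
    """
    by = list(by)
    unknown = set(by) - {"month", "diagnosis", "site"}
    if unknown:
        raise ValueError(f"unknown stratum keys: {sorted(unknown)}")
    rows: list[EvalRow] = []
    for scenario, warnings in warnings_by_scenario.items():
        alerted = [w for w in warnings if w.status == "alerted"]
        rows.append(_row("overall", "overall", scenario,
                         score_episode_level(warnings, gold, catalog, match=match)))
        if "month" in by:
            month_list = list(months) if months is not None else sorted(
                {lb.report_month for lb in gold})
            episodes_of = {m: {lb.episode_id for lb in gold if lb.report_month == m}
                           for m in month_list}
            for m in month_list:
                sub_gold = [lb for lb in gold if lb.report_month == m]
                sub_warn = [w for w in warnings if w.episode_id in episodes_of[m]]
                rows.append(_row("month", m, scenario,
                                 score_episode_level(sub_warn, sub_gold, catalog, match=match)))
        if "diagnosis" in by:
            for d in catalog.diagnosis_codes():
                positive = {lb.episode_id for lb in gold
                            if lb.infected == 1 and lb.diagnosis_code == d}
                predicted = {w.episode_id for w in alerted if w.diagnosis_code == d}
                if not positive and not predicted:
                    continue
                rows.append(_row("diagnosis", d, scenario,
                                 _binary_counts(gold, positive, predicted)))
        if "site" in by:
            for s in catalog.site_codes():
                positive = {lb.episode_id for lb in gold
                            if lb.infected == 1 and lb.site_code == s}
                predicted = {w.episode_id for w in alerted if w.site_code == s}
                if not positive and not predicted:
                    continue
                rows.append(_row("site", s, scenario,
                                 _binary_counts(gold, positive, predicted)))
    return EvalReport(rows=rows)
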