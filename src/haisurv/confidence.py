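"""Monthly confidence feedback for knowledge rules.

Each rule carries a confidence Pr in (0, 1] — the infection probability
attached to its warnings.  After each month of physician review the
confidence is updated from the rule's confirmed-alert accuracy Acc via
the implicit relation

    Pr(i) = Pr(i-1) + alpha * (Acc(i) - Pr(i)) / Pr(i-1)

with adjusting parameter ``alpha`` (0.75 by default).  Because Pr(i)
appears on both sides, the update is solved exactly:

    Pr(i) = (Pr(i-1)^2 + alpha * Acc(i)) / (Pr(i-1) + alpha)

which is self-normalizing to (0, 1], strictly increasing in Acc, and has
Acc = Pr(i-1) as its fixed point; repeated updates under constant Acc
converge to Acc.  An alternative *explicit* reading — substituting
Pr(i-1) for the numerator's Pr(i) — is available via ``form="explicit"``;
that form can leave (0, 1] (e.g. 0.5 + 0.75*(1-0.5)/0.5 = 1.25) and is
therefore clamped to [0.01, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "DEFAULT_ALPHA",
    "rule_accuracy",
    "update_confidence",
    "HistoryEntry",
    "ConfidenceState",
    "FeedbackBatch",
    "monthly_update",
    "read_feedback_csv",
]

DEFAULT_ALPHA = 0.75
EXPLICIT_FLOOR = 0.01


def rule_accuracy(n_alerts: int, n_confirmed: int) -> Optional[float]:
    """Acc = confirmed / alerted for the month; None when nothing alerted.

    A month with no alerts carries the confidence forward unchanged.
    """
    if n_alerts < 0 or n_confirmed < 0:
        raise ValueError("alert/confirmation counts must be non-negative")
    if n_confirmed > n_alerts:
        raise ValueError(f"n_confirmed ({n_confirmed}) exceeds n_alerts ({n_alerts})")
    if n_alerts == 0:
        return None
    return n_confirmed / n_alerts


def update_confidence(pr_prev: float, acc: float, alpha: float = DEFAULT_ALPHA,
                      form: str = "implicit") -> float:
    """One confidence update step.

    ``form="implicit"`` (default) returns the exact solution of the
    implicit update relation; ``form="explicit"`` applies the literal
    explicit step and clamps to [0.01, 1].
    """
    if not (0.0 < pr_prev <= 1.0):
        raise ValueError(f"pr_prev must be in (0, 1], got {pr_prev}")
    if not (0.0 <= acc <= 1.0):
        raise ValueError(f"acc must be in [0, 1], got {acc}")
    if alpha <= 0:
        raise ValueError(f"alpha must be > 0, got {alpha}")
    if form == "implicit":
        return (pr_prev * pr_prev + alpha * acc) / (pr_prev + alpha)
    if form == "explicit":
        out = pr_prev + alpha * (acc - pr_prev) / pr_prev
        return min(1.0, max(EXPLICIT_FLOOR, out))
    raise ValueError(f"form must be 'implicit' or 'explicit', got {form!r}")


@dataclass(frozen=True)
class HistoryEntry:
    month: str  # YYYY-MM
    pr: float
    acc: Optional[float]
    n_alerts: int
    n_confirmed: int


@dataclass
class ConfidenceState:
    """Per-rule confidence with monthly update history."""

    pr: dict[str, float] = field(default_factory=dict)
    history: dict[str, list[HistoryEntry]] = field(default_factory=dict)
    alpha: float = DEFAULT_ALPHA
    form: str = "implicit"

    def __post_init__(self) -> None:
        for rid, p in self.pr.items():
            if not (0.0 < p <= 1.0):
                raise ValueError(f"rule {rid}: confidence {p} outside (0, 1]")

    @classmethod
    def from_rule_base(cls, rule_base, alpha: float = DEFAULT_ALPHA) -> "ConfidenceState":
        return cls(pr={r.rule_id: r.probability for r in rule_base.rules}, alpha=alpha)

    def copy(self) -> "ConfidenceState":
        return ConfidenceState(
            pr=dict(self.pr),
            history={rid: list(entries) for rid, entries in self.history.items()},
            alpha=self.alpha, form=self.form,
        )

    # -- JSON round trip -------------------------------------------------
    def to_json(self, path: Union[str, Path]) -> None:
        data = {
            "alpha": self.alpha,
            "form": self.form,
            "rules": {
                rid: {
                    "pr": p,
                    "history": [
                        {"month": h.month, "pr": h.pr, "acc": h.acc,
                         "n_alerts": h.n_alerts, "n_confirmed": h.n_confirmed}
                        for h in self.history.get(rid, [])
                    ],
                }
                for rid, p in sorted(self.pr.items())
            },
        }
        Path(path).write_text(json.dumps(data, indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "ConfidenceState":
        data = json.loads(Path(path).read_text())
        pr = {rid: entry["pr"] for rid, entry in data["rules"].items()}
        history = {
            rid: [HistoryEntry(**h) for h in entry.get("history", [])]
            for rid, entry in data["rules"].items()
        }
        return cls(pr=pr, history=history,
                   alpha=data.get("alpha", DEFAULT_ALPHA), form=data.get("form", "implicit"))


@dataclass
class FeedbackBatch:
    """One month of review feedback: alert and confirmation counts per rule."""

    month: str  # YYYY-MM
    counts: dict[str, tuple[int, int]]  # rule_id -> (n_alerts, n_confirmed)

    def __post_init__(self) -> None:
        for rid, (na, nc) in self.counts.items():
            if not (0 <= nc <= na):
                raise ValueError(f"rule {rid}: need 0 <= n_confirmed <= n_alerts, got {nc}/{na}")


def read_feedback_csv(path: Union[str, Path]) -> list[FeedbackBatch]:
    """Read feedback batches from CSV (month, rule_id, n_alerts, n_confirmed)."""
    df = pd.read_csv(path, dtype={"month": str, "rule_id": str})
    batches = []
    for month, sub in df.groupby("month", sort=True):
        counts = {r.rule_id: (int(r.n_alerts), int(r.n_confirmed))
                  for r in sub.itertuples(index=False)}
        batches.append(FeedbackBatch(month=month, counts=counts))
    return batches


def monthly_update(state: ConfidenceState, batch: FeedbackBatch) -> ConfidenceState:
    """Apply one month of feedback; returns a new state (input unmutated).

    Rules with alerts that month get the update step; rules without
    alerts (or absent from the batch) carry their confidence forward
    with no history entry.  Batch months must be strictly increasing per
    rule.
    """
    new = state.copy()
    for rid, (n_alerts, n_confirmed) in sorted(batch.counts.items()):
        if rid not in new.pr:
            raise KeyError(f"feedback for unknown rule {rid!r}")
        hist = new.history.setdefault(rid, [])
        if hist and batch.month <= hist[-1].month:
            raise ValueError(
                f"rule {rid}: batch month {batch.month} not after last update {hist[-1].month}")
        acc = rule_accuracy(n_alerts, n_confirmed)
        if acc is None:
            continue
        new.pr[rid] = update_confidence(new.pr[rid], acc, new.alpha, new.form)
        hist.append(HistoryEntry(month=batch.month, pr=new.pr[rid], acc=acc,
                                 n_alerts=n_alerts, n_confirmed=n_confirmed))
    return new
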