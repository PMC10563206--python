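"""Decision-table rule dialect: parsing, validation, packaged exemplars.

Rules are kept in plain-CSV decision tables structurally mirroring the
business-rule decision-table layout common to production-rule engines,
but engine-neutral.  A table file has a five-line header followed by one
data row per rule::

    RuleSet,<ruleset name>
    Diagnosis,<diagnosis code>
    Source,<guideline|expert>
    CONDITION,CONDITION,...,ACTION,ACTION
    <factor_id> <operator>,...,rule_id,probability
    <operand or blank>,...,<id>,<prob>

A blank condition cell means don't-care; every non-blank cell joins the
row's conjunction.  ``in_range`` operands are written ``low..high`` and
denote the half-open interval ``[low, high)``.

Three exemplar tables ship with the package: pleural cavity infection
(PCI, guideline; 5-factor vocabulary including the pleural-effusion
leukocyte cutoff of 1000 x10^6/L), non-catheter urinary tract infection
(UTI, guideline; 7-factor vocabulary with a hospital-days gate) and a
lower-respiratory-tract-infection table from expert practice (LRI;
hospital day, age, presence of a PCT lab, ...).  Cell values not fixed
by the source guideline prose were authored for this package and are
flagged in the provenance sidecar.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

from .catalog import InfectionCatalog
from .factors import FactorRegistry

__all__ = [
    "OPERATORS",
    "Condition",
    "KnowledgeRule",
    "DecisionTable",
    "RuleBase",
    "RuleParseError",
    "parse_decision_table",
    "validate_rule_base",
    "filter_by_source",
    "default_rule_base",
    "SCENARIOS",
]

OPERATORS = ("eq", "ne", "lt", "le", "gt", "ge", "in_range", "contains_flag")
SOURCES = ("guideline", "expert")
SCENARIOS = ("guideline_only", "guideline_plus_expert")


class RuleParseError(ValueError):
    pass


@dataclass(frozen=True)
class Condition:
    """One conjunct: ``factor <operator> operand``.

    ``in_range`` carries a ``(low, high)`` operand and tests the
    half-open interval; ``contains_flag`` tests a binary factor for 1.
    """

    factor_id: str
    operator: str
    operand: object = None

    def __post_init__(self) -> None:
        if self.operator not in OPERATORS:
            raise RuleParseError(f"unknown operator {self.operator!r}")
        if self.operator == "in_range":
            ok = (isinstance(self.operand, tuple) and len(self.operand) == 2
                  and self.operand[0] < self.operand[1])
            if not ok:
                raise RuleParseError(f"in_range operand must be (low, high): {self.operand!r}")


@dataclass(frozen=True)
class KnowledgeRule:
    """One conjunctive rule row with its action (rule id + probability)."""

    rule_id: str
    diagnosis_code: str
    site_code: str
    source: str
    conditions: tuple[Condition, ...]
    probability: float

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise RuleParseError(f"rule {self.rule_id}: source must be guideline|expert")
        if not self.conditions:
            raise RuleParseError(f"rule {self.rule_id}: empty conjunction is forbidden")
        if not (0.0 < self.probability <= 1.0):
            raise RuleParseError(
                f"rule {self.rule_id}: probability {self.probability} outside (0, 1]")


@dataclass
class DecisionTable:
    ruleset_name: str
    diagnosis_code: str
    source: str
    column_bindings: tuple[tuple[str, str], ...]  # (factor_id, operator) per CONDITION col
    rules: tuple[KnowledgeRule, ...]


@dataclass
class RuleBase:
    """A set of knowledge rules with provenance, globally unique ids."""

    rules: tuple[KnowledgeRule, ...]
    provenance: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.rules:
            if r.rule_id in seen:
                raise RuleParseError(f"duplicate rule id: {r.rule_id}")
            seen.add(r.rule_id)

    def by_id(self, rule_id: str) -> KnowledgeRule:
        for r in self.rules:
            if r.rule_id == rule_id:
                return r
        raise KeyError(rule_id)

    def rules_for(self, diagnosis_code: str) -> list[KnowledgeRule]:
        return [r for r in self.rules if r.diagnosis_code == diagnosis_code]

    def diagnoses(self) -> list[str]:
        out: list[str] = []
        for r in self.rules:
            if r.diagnosis_code not in out:
                out.append(r.diagnosis_code)
        return out

    def to_json(self, path: Union[str, Path]) -> None:
        def enc_cond(c: Condition):
            op = list(c.operand) if isinstance(c.operand, tuple) else c.operand
            return {"factor_id": c.factor_id, "operator": c.operator, "operand": op}

        data = [
            {
                "rule_id": r.rule_id,
                "diagnosis_code": r.diagnosis_code,
                "site_code": r.site_code,
                "source": r.source,
                "probability": r.probability,
                "conditions": [enc_cond(c) for c in r.conditions],
            }
            for r in self.rules
        ]
        Path(path).write_text(json.dumps(data, indent=2))


def _parse_operand(cell: str, operator: str) -> object:
    if operator == "in_range":
        try:
            lo, hi = cell.split("..")
            return (float(lo), float(hi))
        except ValueError as exc:
            raise RuleParseError(f"bad in_range operand {cell!r} (want low..high)") from exc
    if operator == "contains_flag":
        return None
    try:
        v = float(cell)
        return int(v) if v.is_integer() else v
    except ValueError:
        return cell  # string operand (eq/ne on coded values)


def parse_decision_table(path: Union[str, Path], registry: FactorRegistry,
                         catalog: InfectionCatalog) -> DecisionTable:
    """Parse one decision-table CSV into validated knowledge rules.

    Errors name the offending row/column: unknown factor, operator/kind
    mismatch, probability outside (0, 1], duplicate or blank rule ids,
    and rows whose condition cells are all blank (empty conjunction).
    """
    path = Path(path)
    with open(path, newline="") as fh:
        raw = [row for row in csv.reader(fh)]
    if len(raw) < 6:
        raise RuleParseError(f"{path.name}: truncated decision table")
    header = {row[0]: (row[1] if len(row) > 1 else "") for row in raw[:3]}
    for key in ("RuleSet", "Diagnosis", "Source"):
        if key not in header:
            raise RuleParseError(f"{path.name}: missing {key} header line")
    diagnosis = header["Diagnosis"]
    source = header["Source"]
    site = catalog.site_of(diagnosis)  # raises on unknown diagnosis
    kinds = raw[3]
    bindings_row = raw[4]
    if len(kinds) != len(bindings_row):
        raise RuleParseError(f"{path.name}: column-kind and binding rows differ in length")
    cond_cols: list[tuple[int, str, str]] = []
    action_cols: dict[str, int] = {}
    for i, kind in enumerate(kinds):
        if kind == "CONDITION":
            parts = bindings_row[i].split()
            if len(parts) != 2:
                raise RuleParseError(
                    f"{path.name} column {i + 1}: binding must be '<factor> <operator>'")
            fid, op = parts
            if fid not in registry:
                raise RuleParseError(f"{path.name} column {i + 1}: unknown factor {fid!r}")
            if op not in OPERATORS:
                raise RuleParseError(f"{path.name} column {i + 1}: unknown operator {op!r}")
            spec = registry[fid]
            if op == "in_range" and spec.kind not in ("integer", "real"):
                raise RuleParseError(
                    f"{path.name} column {i + 1}: in_range needs a numeric factor, {fid} is {spec.kind}")
            cond_cols.append((i, fid, op))
        elif kind == "ACTION":
            action_cols[bindings_row[i]] = i
        elif kind.strip():
            raise RuleParseError(f"{path.name} column {i + 1}: column kind must be CONDITION or ACTION")
    for needed in ("rule_id", "probability"):
        if needed not in action_cols:
            raise RuleParseError(f"{path.name}: missing ACTION column {needed!r}")

    rules: list[KnowledgeRule] = []
    seen_ids: set[str] = set()
    for rownum, row in enumerate(raw[5:], start=6):
        if not any(cell.strip() for cell in row):
            continue
        conds = []
        for i, fid, op in cond_cols:
            cell = row[i].strip() if i < len(row) else ""
            if not cell and op != "contains_flag":
                continue
            if op == "contains_flag" and not cell:
                continue
            conds.append(Condition(factor_id=fid, operator=op, operand=_parse_operand(cell, op)))
        if not conds:
            raise RuleParseError(f"{path.name} row {rownum}: all condition cells blank")
        rid = row[action_cols["rule_id"]].strip()
        if not rid:
            raise RuleParseError(f"{path.name} row {rownum}: blank rule_id")
        if rid in seen_ids:
            raise RuleParseError(f"{path.name} row {rownum}: duplicate rule id {rid!r}")
        seen_ids.add(rid)
        try:
            prob = float(row[action_cols["probability"]])
        except ValueError as exc:
            raise RuleParseError(f"{path.name} row {rownum}: bad probability") from exc
        rules.append(
            KnowledgeRule(rule_id=rid, diagnosis_code=diagnosis, site_code=site,
                          source=source, conditions=tuple(conds), probability=prob)
        )
    return DecisionTable(
        ruleset_name=header["RuleSet"], diagnosis_code=diagnosis, source=source,
        column_bindings=tuple((fid, op) for _, fid, op in cond_cols), rules=tuple(rules),
    )


def write_decision_table(table: DecisionTable, path: Union[str, Path]) -> None:
    """Serialize a table back to the CSV dialect (inverse of the parser)."""
    cols = list(table.column_bindings)
    n = len(cols) + 2
    rows: list[list[str]] = [
        ["RuleSet", table.ruleset_name] + [""] * (n - 2),
        ["Diagnosis", table.diagnosis_code] + [""] * (n - 2),
        ["Source", table.source] + [""] * (n - 2),
        ["CONDITION"] * len(cols) + ["ACTION", "ACTION"],
        [f"{fid} {op}" for fid, op in cols] + ["rule_id", "probability"],
    ]
    for rule in table.rules:
        by_factor = {(c.factor_id, c.operator): c for c in rule.conditions}
        cells = []
        for fid, op in cols:
            c = by_factor.get((fid, op))
            if c is None:
                cells.append("")
            elif op == "in_range":
                cells.append(f"{c.operand[0]}..{c.operand[1]}")
            elif op == "contains_flag":
                cells.append("x")
            else:
                cells.append(str(c.operand))
        rows.append(cells + [rule.rule_id, repr(rule.probability)])
    with open(path, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)


def load_rule_base(paths: Iterable[Union[str, Path]], registry: FactorRegistry,
                   catalog: InfectionCatalog,
                   provenance: Optional[dict] = None) -> RuleBase:
    rules: list[KnowledgeRule] = []
    prov: dict[str, dict] = dict(provenance or {})
    for p in paths:
        table = parse_decision_table(p, registry, catalog)
        for i, r in enumerate(table.rules, start=1):
            rules.append(r)
            prov.setdefault(r.rule_id, {"file": Path(p).name, "row": i})
    return RuleBase(rules=tuple(rules), provenance=prov)


def validate_rule_base(rules: Union[RuleBase, Iterable[KnowledgeRule]],
                       catalog: InfectionCatalog,
                       registry: FactorRegistry) -> list[str]:
    """Cross-check rules against catalog and registry; returns issue strings."""
    rule_list = list(rules.rules if isinstance(rules, RuleBase) else rules)
    issues: list[str] = []
    seen: set[str] = set()
    for r in rule_list:
        if r.rule_id in seen:
            issues.append(f"duplicate rule id: {r.rule_id}")
        seen.add(r.rule_id)
        if r.diagnosis_code not in catalog:
            issues.append(f"rule {r.rule_id}: unknown diagnosis {r.diagnosis_code!r}")
        elif catalog.site_of(r.diagnosis_code) != r.site_code:
            issues.append(f"rule {r.rule_id}: site {r.site_code!r} does not own {r.diagnosis_code!r}")
        if not (0.0 < r.probability <= 1.0):
            issues.append(f"rule {r.rule_id}: probability {r.probability} outside (0, 1]")
        for c in r.conditions:
            spec = registry.get(c.factor_id)
            if spec is None:
                issues.append(f"rule {r.rule_id}: unknown factor {c.factor_id!r}")
                continue
            if c.operator == "in_range" and spec.kind not in ("integer", "real"):
                issues.append(f"rule {r.rule_id}: in_range on non-numeric factor {c.factor_id!r}")
            if spec.kind == "binary" and c.operator in ("eq", "ne") and c.operand not in (0, 1):
                issues.append(f"rule {r.rule_id}: binary factor {c.factor_id!r} compared to {c.operand!r}")
    return issues


def filter_by_source(rules: RuleBase, scenario: str) -> RuleBase:
    """Restrict a rule base to an evaluation scenario.

    ``guideline_only`` keeps guideline-derived rules; the combined
    scenario ``guideline_plus_expert`` keeps everything.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; want one of {SCENARIOS}")
    if scenario == "guideline_plus_expert":
        kept = rules.rules
    else:
        kept = tuple(r for r in rules.rules if r.source == "guideline")
    return RuleBase(rules=kept,
                    provenance={r.rule_id: rules.provenance.get(r.rule_id, {}) for r in kept})


def default_rule_base(registry: Optional[FactorRegistry] = None,
                      catalog: Optional[InfectionCatalog] = None) -> RuleBase:
    """The packaged exemplar rule base (PCI + UTI guideline, LRI expert)."""
    from .catalog import default_catalog
    from .factors import default_registry

    registry = registry or default_registry()
    catalog = catalog or default_catalog()
    data_dir = resources.files("haisurv.data") / "rules"
    prov_text = (data_dir / "provenance.json").read_text()
    provenance = {k: v for k, v in json.loads(prov_text).items() if not k.startswith("_")}
    rules: list[KnowledgeRule] = []
    for name in ("pci_guideline.csv", "uti_guideline.csv", "lri_expert.csv"):
        with resources.as_file(data_dir / name) as p:
            table = parse_decision_table(p, registry, catalog)
        for i, r in enumerate(table.rules, start=1):
            rules.append(r)
            provenance.setdefault(r.rule_id, {"file": name, "row": i})
    return RuleBase(rules=tuple(rules), provenance=provenance)
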