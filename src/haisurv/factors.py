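"""Factor registry and typed factor values.

A *factor* is one infection-related observable (highest daily body
temperature, urinary leukocyte abnormal flag, presence of a PCT lab,
...).  The registry declares, for every known factor id, its value kind
(``integer`` | ``real`` | ``date`` | ``binary``), its unit and the
case-tuple group it lives in.  Rules may only reference registered
factors; unregistered factors in a case are reported as validation
issues, never raised.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Union

import yaml

__all__ = ["FactorKind", "FactorSpec", "FactorValue", "FactorRegistry", "load_registry", "default_registry"]

FACTOR_KINDS = ("integer", "real", "date", "binary")
FactorKind = str


@dataclass(frozen=True)
class FactorSpec:
    id: str
    kind: FactorKind
    unit: str
    group: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.kind not in FACTOR_KINDS:
            raise ValueError(f"factor {self.id!r}: unknown kind {self.kind!r}")


@dataclass(frozen=True)
class FactorValue:
    """One observed factor value.

    Binary values are exactly 0 or 1; numeric values carry the declared
    unit where applicable; dates are naive calendar timestamps.
    """

    factor_id: str
    kind: FactorKind
    value: Any
    unit: str = ""

    def check(self) -> Optional[str]:
        """Return a violation message, or None when the value is in-domain."""
        v = self.value
        if self.kind == "binary":
            if v not in (0, 1):
                return f"binary out of domain: {self.factor_id}={v!r}"
        elif self.kind == "integer":
            if not isinstance(v, int) or isinstance(v, bool):
                return f"integer expected: {self.factor_id}={v!r}"
        elif self.kind == "real":
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                return f"real expected: {self.factor_id}={v!r}"
        elif self.kind == "date":
            if not isinstance(v, (dt.date, dt.datetime)):
                return f"date expected: {self.factor_id}={v!r}"
            if isinstance(v, dt.datetime) and v.tzinfo is not None:
                return f"date must be timezone-naive: {self.factor_id}"
        return None


class FactorRegistry:
    """Lookup table of :class:`FactorSpec` by factor id."""

    def __init__(self, specs: list[FactorSpec]):
        self._specs: dict[str, FactorSpec] = {}
        for spec in specs:
            if spec.id in self._specs:
                raise ValueError(f"duplicate factor id: {spec.id!r}")
            self._specs[spec.id] = spec

    def __contains__(self, factor_id: str) -> bool:
        return factor_id in self._specs

    def __getitem__(self, factor_id: str) -> FactorSpec:
        return self._specs[factor_id]

    def __iter__(self):
        return iter(self._specs.values())

    def __len__(self) -> int:
        return len(self._specs)

    def get(self, factor_id: str) -> Optional[FactorSpec]:
        return self._specs.get(factor_id)

    def make(self, factor_id: str, value: Any) -> FactorValue:
        """Build a FactorValue typed per the registry entry."""
        spec = self._specs[factor_id]
        return FactorValue(factor_id=factor_id, kind=spec.kind, value=value, unit=spec.unit)


def load_registry(path: Union[str, Path]) -> FactorRegistry:
    data = yaml.safe_load(Path(path).read_text())
    return _registry_from_dict(data, source=str(path))


def _registry_from_dict(data: dict, source: str = "<registry>") -> FactorRegistry:
    if not isinstance(data, dict) or "factors" not in data:
        raise ValueError(f"{source}: registry file must contain a top-level 'factors' list")
    specs = [
        FactorSpec(
            id=str(f["id"]),
            kind=str(f["kind"]),
            unit=str(f.get("unit", "")),
            group=str(f["group"]),
            description=str(f.get("description", "")),
        )
        for f in data["factors"]
    ]
    return FactorRegistry(specs)


def default_registry() -> FactorRegistry:
    """The packaged registry seeding every factor the exemplar rules use."""
    ref = resources.files("haisurv.data") / "factor_registry.yaml"
    return _registry_from_dict(yaml.safe_load(ref.read_text()), source="factor_registry.yaml")
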