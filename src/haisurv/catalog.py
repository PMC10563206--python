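"""Infection catalog: sites and the diagnoses belonging to each site.

The catalog is the controlled vocabulary of the whole pipeline: every
knowledge rule targets one diagnosis code, every warning carries the
diagnosis plus its (unique) owning site, and the evaluation strata are
keyed by these codes.  The packaged default transcribes the standard
12-site / 40-diagnosis classification used for hospital-acquired
infection reporting in China (e.g. site ``RTI`` owns ``UR``, ``LRI``,
``PCI`` and ``VAP``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Union

import yaml

__all__ = [
    "DiagnosisEntry",
    "SiteEntry",
    "InfectionCatalog",
    "CatalogError",
    "load_catalog",
    "default_catalog",
]


class CatalogError(ValueError):
    """Raised when a catalog file violates a structural invariant."""


@dataclass(frozen=True)
class DiagnosisEntry:
    code: str
    name: str


@dataclass(frozen=True)
class SiteEntry:
    code: str
    name: str
    diagnoses: tuple[DiagnosisEntry, ...]


@dataclass
class InfectionCatalog:
    """Validated collection of infection sites and their diagnoses.

    Invariants enforced at construction: site codes distinct, diagnosis
    codes distinct, and every diagnosis belongs to exactly one site.
    """

    sites: tuple[SiteEntry, ...]
    _site_of: dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        seen_sites: set[str] = set()
        site_of: dict[str, str] = {}
        for site in self.sites:
            if site.code in seen_sites:
                raise CatalogError(f"duplicate site code: {site.code!r}")
            seen_sites.add(site.code)
            for diag in site.diagnoses:
                if diag.code in site_of:
                    raise CatalogError(f"duplicate diagnosis code: {diag.code!r}")
                site_of[diag.code] = site.code
        object.__setattr__(self, "_site_of", site_of)

    # -- queries ---------------------------------------------------------
    def site_codes(self) -> list[str]:
        return [s.code for s in self.sites]

    def diagnosis_codes(self) -> list[str]:
        return [d.code for s in self.sites for d in s.diagnoses]

    def site_of(self, diagnosis_code: str) -> str:
        """Unique owning site of a diagnosis code."""
        try:
            return self._site_of[diagnosis_code]
        except KeyError:
            raise CatalogError(f"unknown diagnosis code: {diagnosis_code!r}") from None

    def diagnoses_for_site(self, site_code: str) -> list[str]:
        for site in self.sites:
            if site.code == site_code:
                return [d.code for d in site.diagnoses]
        raise CatalogError(f"unknown site code: {site_code!r}")

    def __contains__(self, diagnosis_code: str) -> bool:
        return diagnosis_code in self._site_of

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "sites": [
                {
                    "code": s.code,
                    "name": s.name,
                    "diagnoses": [{"code": d.code, "name": d.name} for d in s.diagnoses],
                }
                for s in self.sites
            ]
        }

    @classmethod
    def from_dict(cls, data: dict) -> "InfectionCatalog":
        try:
            sites = tuple(
                SiteEntry(
                    code=str(s["code"]),
                    name=str(s["name"]),
                    diagnoses=tuple(
                        DiagnosisEntry(code=str(d["code"]), name=str(d["name"]))
                        for d in s.get("diagnoses", [])
                    ),
                )
                for s in data["sites"]
            )
        except (KeyError, TypeError) as exc:
            raise CatalogError(f"malformed catalog structure: {exc}") from exc
        return cls(sites=sites)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def load_catalog(path: Union[str, Path]) -> InfectionCatalog:
    """Load and validate a catalog from a YAML (or JSON) file."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "sites" not in data:
        raise CatalogError(f"{path}: catalog file must contain a top-level 'sites' list")
    return InfectionCatalog.from_dict(data)


def default_catalog() -> InfectionCatalog:
    """The packaged 12-site / 40-diagnosis catalog."""
    ref = resources.files("haisurv.data") / "catalog_default.yaml"
    return InfectionCatalog.from_dict(yaml.safe_load(ref.read_text()))
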