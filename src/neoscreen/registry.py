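"""Disease registry: marker analytes, deviation directions and prevalences.

A :class:`DiseaseDefinition` ties an inherited metabolic disease (IMD) to the
panel analytes that mark it, the direction in which affected values deviate
from the healthy range (e.g. phenylalanine is raised in PAHD, free carnitine
is lowered in primary carnitine deficiency), its prevalence among screened
newborns, and per-zygosity concentration statistics used by the synthetic
cohort generator. The default registry ships 16 IMDs.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .panel import DEFAULT_ANALYTES, UnknownAnalyteError, validate_analyte

HIGH = "high"
LOW = "low"

AFFECTED = "affected"
CARRIER = "carrier"
UNAFFECTED = "unaffected"

#: Zygosity classes a subject can hold for a disease.
ZYGOSITY_CLASSES = (AFFECTED, CARRIER, UNAFFECTED)


class RegistryValidationError(ValueError):
    """Raised when a disease registry entry violates its invariants."""


@dataclass(frozen=True)
class Marker:
    """A marker analyte and the side on which disease shifts it."""

    analyte: str
    direction: str  # "high" or "low"

    def __post_init__(self) -> None:
        if self.direction not in (HIGH, LOW):
            raise RegistryValidationError(
                f"marker direction must be 'high' or 'low', got {self.direction!r}"
            )


@dataclass(frozen=True)
class ClassParams:
    """Mean/SD (μmol/L) of one marker analyte in one zygosity class."""

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise RegistryValidationError(f"sd must be >= 0, got {self.sd}")
        if self.mean < 0:
            raise RegistryValidationError(f"mean must be >= 0, got {self.mean}")


@dataclass(frozen=True)
class DiseaseDefinition:
    abbreviation: str
    genes: tuple[str, ...]
    markers: tuple[Marker, ...]
    prevalence: float
    affected_params: Mapping[str, ClassParams] = field(default_factory=dict)
    carrier_params: Mapping[str, ClassParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise RegistryValidationError(
                f"{self.abbreviation}: prevalence must lie in (0, 1), got {self.prevalence}"
            )
        if not self.markers:
            raise RegistryValidationError(f"{self.abbreviation}: at least one marker required")
        marker_names = {m.analyte for m in self.markers}
        for params, label in ((self.affected_params, "affected"), (self.carrier_params, "carrier")):
            missing = marker_names - set(params)
            if missing:
                raise RegistryValidationError(
                    f"{self.abbreviation}: {label} params missing for markers {sorted(missing)}"
                )

    def marker_direction(self, analyte: str) -> str:
        for m in self.markers:
            if m.analyte == analyte:
                return m.direction
        raise KeyError(analyte)

    def params_for(self, zygosity: str) -> Mapping[str, ClassParams]:
        if zygosity == AFFECTED:
            return self.affected_params
        if zygosity == CARRIER:
            return self.carrier_params
        raise ValueError(f"no marker params for zygosity {zygosity!r}")


def _parse_params(raw: Mapping, abbr: str, label: str) -> dict[str, ClassParams]:
    out: dict[str, ClassParams] = {}
    for analyte, stats in (raw or {}).items():
        try:
            validate_analyte(analyte)
        except UnknownAnalyteError as exc:
            raise UnknownAnalyteError(f"{abbr} ({label}): {exc}") from exc
        out[analyte] = ClassParams(mean=float(stats["mean"]), sd=float(stats["sd"]))
    return out


def _parse_disease(entry: Mapping) -> DiseaseDefinition:
    abbr = str(entry["abbr"])
    markers = []
    for m in entry["markers"]:
        analyte = m["analyte"]
        try:
            validate_analyte(analyte)
        except UnknownAnalyteError as exc:
            raise UnknownAnalyteError(f"{abbr}: {exc}") from exc
        markers.append(Marker(analyte=analyte, direction=m["direction"]))
    return DiseaseDefinition(
        abbreviation=abbr,
        genes=tuple(entry.get("genes", ())),
        markers=tuple(markers),
        prevalence=float(entry["prevalence"]),
        affected_params=_parse_params(entry.get("affected", {}), abbr, "affected"),
        carrier_params=_parse_params(entry.get("carrier", {}), abbr, "carrier"),
    )


def _default_registry_text() -> str:
    return (
        importlib.resources.files("neoscreen.data").joinpath("diseases.yaml").read_text()
    )


def build_disease_registry(config: str | Path | Mapping | None = None) -> list[DiseaseDefinition]:
    """Build the disease registry from a YAML/JSON mapping or file path.

    With ``config=None`` the packaged default registry of 16 IMDs is used.
    The mapping must have a top-level ``diseases`` list; each entry carries
    ``abbr``, ``genes``, ``markers`` (analyte + direction), ``prevalence``
    and per-class marker statistics under ``affected`` / ``carrier``.
    """
    if config is None:
        raw = yaml.safe_load(_default_registry_text())
    elif isinstance(config, (str, Path)):
        raw = yaml.safe_load(Path(config).read_text())
    else:
        raw = config
    entries = raw.get("diseases", []) if isinstance(raw, Mapping) else raw
    registry = [_parse_disease(e) for e in entries]
    seen: set[str] = set()
    for d in registry:
        if d.abbreviation in seen:
            raise RegistryValidationError(f"duplicate disease {d.abbreviation}")
        seen.add(d.abbreviation)
    return registry


def total_prevalence(registry: Sequence[DiseaseDefinition], carrier_multiplier: float = 1.0) -> float:
    """Total probability mass assigned to affected plus carrier classes."""
    base = sum(d.prevalence for d in registry)
    return base * (1.0 + carrier_multiplier)


def registry_by_abbr(registry: Iterable[DiseaseDefinition]) -> dict[str, DiseaseDefinition]:
    return {d.abbreviation: d for d in registry}
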