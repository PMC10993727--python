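"""Analyte panel schema for the dried-blood-spot MS/MS screen.

The panel quantifies 11 amino acids, 31 acylcarnitines and succinylacetone
(43 analytes total), all in μmol/L of whole blood eluted from the dried
blood spot. Analyte order is fixed by this module and is the canonical
column order everywhere else in the package.
"""

from __future__ import annotations

from typing import Iterable, Mapping

AMINO_ACIDS: tuple[str, ...] = (
    "ALA", "ARG", "CIT", "GLY", "LEU", "MET", "ORN", "PHE", "PRO", "TYR", "VAL",
)

ACYLCARNITINES: tuple[str, ...] = (
    "C0", "C2", "C3", "C3DC", "C4", "C4DC", "C4OH",
    "C5", "C5:1", "C5DC", "C5OH",
    "C6", "C6DC", "C8", "C8:1",
    "C10", "C10:1", "C10:2",
    "C12", "C12:1",
    "C14", "C14:1", "C14:2", "C14OH",
    "C16", "C16:1", "C16OH", "C16:1OH",
    "C18", "C18:1", "C18:2",
)

SUCCINYLACETONE: str = "SA"

#: Canonical analyte ordering: amino acids, acylcarnitines, succinylacetone.
DEFAULT_ANALYTES: tuple[str, ...] = AMINO_ACIDS + ACYLCARNITINES + (SUCCINYLACETONE,)

assert len(AMINO_ACIDS) == 11
assert len(ACYLCARNITINES) == 31
assert len(DEFAULT_ANALYTES) == 43


class UnknownAnalyteError(ValueError):
    """Raised when a configuration references an analyte not in the panel."""


def validate_analyte(name: str, panel: Iterable[str] = DEFAULT_ANALYTES) -> str:
    if name not in set(panel):
        raise UnknownAnalyteError(f"unknown analyte {name!r}: not in the panel schema")
    return name


def validate_panel(panel: Mapping[str, float], analytes: Iterable[str] = DEFAULT_ANALYTES) -> None:
    """Check a concentration mapping covers the full panel with finite, non-negative values."""
    missing = [a for a in analytes if a not in panel]
    if missing:
        raise UnknownAnalyteError(f"panel missing analytes: {', '.join(missing)}")
    for name, value in panel.items():
        if value < 0:
            raise ValueError(f"negative concentration for {name}: {value}")
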