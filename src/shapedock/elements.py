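"""Van der Waals radius tables.

The molecular solid is the union of atom-centered vdW spheres, so the radius
set directly determines volume, surface area and every moment descriptor
derived from them. The default is Bondi's consistent set (J. Phys. Chem. 68,
441, 1964) extended with a handful of later main-group values; a custom table
can be loaded from a two-column ``element,radius`` CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ElementResolutionError

# Bondi (1964) plus common extensions (Mantina et al. 2009 for Si, Se ...).
# Radii in Angstrom.
_BONDI: dict[str, float] = {
    "H": 1.20,
    "He": 1.40,
    "B": 1.92,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "Ne": 1.54,
    "Na": 2.27,
    "Mg": 1.73,
    "Al": 1.84,
    "Si": 2.10,
    "P": 1.80,
    "S": 1.80,
    "Cl": 1.75,
    "Ar": 1.88,
    "K": 2.75,
    "Ca": 2.31,
    "Zn": 1.39,
    "Ga": 1.87,
    "As": 1.85,
    "Se": 1.90,
    "Br": 1.85,
    "Kr": 2.02,
    "Te": 2.06,
    "I": 1.98,
    "Xe": 2.16,
}

_REQUIRED = ("H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I")


def _normalize_symbol(symbol: str) -> str:
    s = symbol.strip()
    if not s:
        return s
    return s[0].upper() + s[1:].lower()


@dataclass(frozen=True)
class VdwRadiusTable:
    """Mapping element symbol -> vdW radius (Angstrom) with a provenance label."""

    radii: dict[str, float]
    label: str

    def __post_init__(self) -> None:
        missing = [e for e in _REQUIRED if e not in self.radii]
        if missing:
            raise ValueError(f"radius table '{self.label}' missing elements: {missing}")
        bad = {e: r for e, r in self.radii.items() if not r > 0}
        if bad:
            raise ValueError(f"non-positive radii in table '{self.label}': {bad}")

    def radius(self, element: str) -> float:
        sym = _normalize_symbol(element)
        try:
            return self.radii[sym]
        except KeyError:
            raise ElementResolutionError(
                f"element '{element}' not in radius table '{self.label}'"
            ) from None

    def __contains__(self, element: str) -> bool:
        return _normalize_symbol(element) in self.radii

    @property
    def max_radius(self) -> float:
        return max(self.radii.values())


BONDI = VdwRadiusTable(radii=dict(_BONDI), label="bondi")


def load_radius_table(path: str | Path, label: str | None = None) -> VdwRadiusTable:
    """Load a custom radius table from an ``element,radius`` CSV (no header)."""
    path = Path(path)
    radii: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row or row[0].lstrip().startswith("#"):
                continue
            radii[_normalize_symbol(row[0])] = float(row[1])
    return VdwRadiusTable(radii=radii, label=label or path.stem)
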