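"""Carbon-scaled atomic property weights (mass / electronegativity / volume).

Every weighting scheme divides the raw per-element constant by the carbon
value, so a carbon atom always weighs exactly 1.0 and a uniform rescaling
of the underlying table leaves all weights unchanged.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np

from ..errors import QsarPipeError
from .model import Molecule

#: scheme letter -> column in the property table
SCHEMES = {"m": "mass", "e": "sanderson_en", "v": "vdw_volume"}


class UnknownElementError(QsarPipeError):
    """An element has no tabulated value for the requested scheme."""


@dataclass(frozen=True)
class WeightTable:
    """Raw per-element constants for one scheme plus the carbon reference."""

    scheme: str
    values: dict[str, float]
    carbon_reference: float

    def __post_init__(self):
        if self.scheme not in SCHEMES:
            raise QsarPipeError(f"unknown weighting scheme {self.scheme!r}; "
                                f"expected one of {sorted(SCHEMES)}")
        if self.carbon_reference <= 0 or any(v <= 0 for v in self.values.values()):
            raise QsarPipeError("property table values must be strictly positive")

    def scaled(self, element: str) -> float:
        try:
            return self.values[element] / self.carbon_reference
        except KeyError:
            raise UnknownElementError(
                f"element {element!r} is not tabulated for scheme {self.scheme!r}"
            ) from None


def load_property_tables(path: str | None = None) -> dict[str, WeightTable]:
    """Read the delimited property table; ``path=None`` uses the bundled one.

    The file has columns element, mass, sanderson_en, vdw_volume; lines
    beginning with ``#`` are comments.
    """
    if path is None:
        text = (resources.files("qsarpipe") / "data/atomic_properties.csv").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    rows = [r for r in text.splitlines() if r.strip() and not r.startswith("#")]
    reader = csv.DictReader(rows)
    raw: dict[str, dict[str, float]] = {c: {} for c in SCHEMES.values()}
    for rec in reader:
        el = rec["element"].strip()
        for col in SCHEMES.values():
            raw[col][el] = float(rec[col])
    tables = {}
    for letter, col in SCHEMES.items():
        if "C" not in raw[col]:
            raise QsarPipeError(f"property table lacks a carbon entry for {col}")
        tables[letter] = WeightTable(letter, raw[col], raw[col]["C"])
    return tables


_DEFAULT_TABLES: dict[str, WeightTable] | None = None


def default_tables() -> dict[str, WeightTable]:
    global _DEFAULT_TABLES
    if _DEFAULT_TABLES is None:
        _DEFAULT_TABLES = load_property_tables()
    return _DEFAULT_TABLES


def scaled_weights(
    mol: Molecule,
    scheme: str,
    tables: dict[str, WeightTable] | None = None,
    indices: list[int] | None = None,
) -> np.ndarray:
    """Per-atom carbon-scaled weights for ``scheme`` ('m', 'e' or 'v').

    ``indices`` restricts the output to the given atom indices (e.g. the
    heavy-atom view); default is every atom in order.
    """
    table = (tables or default_tables())[scheme]
    if indices is None:
        indices = list(range(mol.num_atoms))
    return np.array([table.scaled(mol.atoms[i].element) for i in indices])
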