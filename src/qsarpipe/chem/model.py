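"""Molecular data model: atoms, bonds and the molecule container.

Atom indices are 0-based in memory; all file I/O follows the SDF
convention of 1-based indices. Coordinates are Cartesian angstroms.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import MoleculeError

#: elements recognised by the default property tables
KNOWN_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)


@dataclass(frozen=True)
class Atom:
    """A single atom: element symbol, position (angstrom) and aromatic flag."""

    element: str
    position: tuple[float, float, float]
    is_aromatic: bool = False
    index: int = 0

    def __post_init__(self):
        if not all(np.isfinite(self.position)):
            raise MoleculeError(
                f"atom {self.index} ({self.element}) has non-finite coordinates"
            )


@dataclass(frozen=True)
class Bond:
    """Bond between two 0-based atom indices; order 1, 2, 3 or 1.5 (aromatic)."""

    i: int
    j: int
    order: float = 1.0


@dataclass
class Molecule:
    """An ordered atom list plus bonds, as read from a structure file.

    ``has_coordinates`` is False for records read from SMILES until
    :func:`qsarpipe.chem.io.embed_coordinates` assigns a 3D geometry.
    """

    atoms: list[Atom]
    bonds: list[Bond]
    identifier: str = ""
    has_coordinates: bool = True
    properties: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.atoms)
        for b in self.bonds:
            if not (0 <= b.i < n and 0 <= b.j < n) or b.i == b.j:
                raise MoleculeError(
                    f"molecule {self.identifier!r}: bond ({b.i}, {b.j}) "
                    f"references invalid atom indices (n={n})"
                )
        if self.num_heavy_atoms == 0:
            raise MoleculeError(
                f"molecule {self.identifier!r} has no heavy atoms"
            )

    # -- views ---------------------------------------------------------------

    @property
    def num_atoms(self) -> int:
        return len(self.atoms)

    @property
    def num_heavy_atoms(self) -> int:
        return len(self.heavy_indices())

    def heavy_indices(self) -> list[int]:
        return [a.index for a in self.atoms if a.element != "H"]

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def coordinates(self) -> np.ndarray:
        """(N, 3) array of positions; raises if coordinates are absent."""
        if not self.has_coordinates:
            raise MoleculeError(
                f"molecule {self.identifier!r} has no 3D coordinates; "
                "call embed_coordinates first"
            )
        return np.array([a.position for a in self.atoms], dtype=float)

    def adjacency(self, hydrogen_depleted: bool = False) -> tuple[np.ndarray, list[int]]:
        """Binary adjacency matrix and the original indices of its rows.

        With ``hydrogen_depleted`` the matrix covers heavy atoms only and
        the returned index list maps matrix rows back to molecule indices.
        """
        if hydrogen_depleted:
            keep = self.heavy_indices()
        else:
            keep = list(range(self.num_atoms))
        pos = {orig: row for row, orig in enumerate(keep)}
        adj = np.zeros((len(keep), len(keep)), dtype=np.int8)
        for b in self.bonds:
            if b.i in pos and b.j in pos:
                adj[pos[b.i], pos[b.j]] = 1
                adj[pos[b.j], pos[b.i]] = 1
        return adj, keep

    def degrees(self, hydrogen_depleted: bool = True) -> np.ndarray:
        adj, _ = self.adjacency(hydrogen_depleted)
        return adj.sum(axis=1)
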