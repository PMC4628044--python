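"""Topological (bond-count) distance matrices."""
from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import shortest_path

from ..errors import MoleculeError
from .model import Molecule


def topological_distances(mol: Molecule, hydrogen_depleted: bool = False) -> np.ndarray:
    """All-pairs shortest path lengths in bonds for the requested graph view.

    Returns an integer matrix over the atoms of the view, ordered as in the
    molecule.  Raises :class:`MoleculeError` if that view is disconnected.
    """
    adj, keep = mol.adjacency(hydrogen_depleted)
    if len(keep) == 1:
        return np.zeros((1, 1), dtype=int)
    dist = shortest_path(adj, method="D", unweighted=True, directed=False)
    if np.isinf(dist).any():
        view = "hydrogen-depleted" if hydrogen_depleted else "full"
        raise MoleculeError(
            f"molecule {mol.identifier!r}: {view} graph is disconnected"
        )
    return dist.astype(int)
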