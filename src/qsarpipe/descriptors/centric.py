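"""Lopping centric index: entropy of the terminal-pruning partition."""
from __future__ import annotations

import numpy as np

from ..chem.model import Molecule


def pruning_partition(mol: Molecule) -> list[int]:
    """Sizes of the vertex classes removed by iterative terminal pruning.

    Each step removes every vertex of degree <= 1 from the hydrogen-depleted
    graph.  Vertices that survive all pruning (pure rings) are removed
    together as one final class, so the partition always covers all heavy
    atoms.
    """
    adj, keep = mol.adjacency(hydrogen_depleted=True)
    alive = np.ones(len(keep), dtype=bool)
    partition: list[int] = []
    while alive.any():
        degrees = adj[np.ix_(alive, alive)].sum(axis=1)
        terminal = degrees <= 1
        if terminal.any():
            removed = int(terminal.sum())
            alive_idx = np.flatnonzero(alive)
            alive[alive_idx[terminal]] = False
        else:
            removed = int(alive.sum())  # remaining rings drop as one class
            alive[:] = False
        partition.append(removed)
    return partition


def lopping_centric_index(mol: Molecule) -> float:
    """Lop = -sum_g (n_g / A) * log2(n_g / A) over the pruning partition."""
    partition = pruning_partition(mol)
    total = sum(partition)
    fractions = np.array(partition, dtype=float) / total
    return float(-(fractions * np.log2(fractions)).sum())
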