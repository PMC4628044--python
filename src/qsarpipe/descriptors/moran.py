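"""Moran spatial autocorrelation over the hydrogen-depleted molecular graph."""
from __future__ import annotations

import logging

from ..chem.graph import topological_distances
from ..chem.model import Molecule
from ..chem.weights import WeightTable, scaled_weights
from ..errors import DescriptorError

log = logging.getLogger(__name__)


def moran_autocorrelation(
    mol: Molecule,
    lag: int,
    scheme: str,
    tables: dict[str, WeightTable] | None = None,
) -> float:
    """Moran index at topological ``lag`` with carbon-scaled atomic weights.

    Heavy atoms only.  With w the scaled weights, A the heavy-atom count
    and Delta the number of unordered pairs at exactly ``lag`` bonds::

        I = [ (1/Delta) sum_{d_ij = lag} (w_i - wbar)(w_j - wbar) ]
            / [ (1/A) sum_i (w_i - wbar)^2 ]

    No pairs at the lag returns 0 (logged); zero weight variance raises
    :class:`DescriptorError`.
    """
    if lag < 1:
        raise DescriptorError(f"lag must be >= 1, got {lag}", descriptor="MATS")
    heavy = mol.heavy_indices()
    if len(heavy) < 2:
        raise DescriptorError("need at least 2 heavy atoms", descriptor="MATS")
    dist = topological_distances(mol, hydrogen_depleted=True)
    w = scaled_weights(mol, scheme, tables, indices=heavy)
    centered = w - w.mean()

    pairs = [(i, j) for i in range(len(heavy)) for j in range(i + 1, len(heavy))
             if dist[i, j] == lag]
    if not pairs:
        log.warning("%s: no atom pairs at lag %d; returning 0",
                    mol.identifier or "<molecule>", lag)
        return 0.0

    variance = float((centered ** 2).sum()) / len(heavy)
    if variance == 0.0:
        raise DescriptorError(
            f"all heavy-atom weights equal under scheme {scheme!r}; "
            "Moran index undefined", descriptor="MATS")

    cross = sum(centered[i] * centered[j] for i, j in pairs) / len(pairs)
    return float(cross / variance)
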