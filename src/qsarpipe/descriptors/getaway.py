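"""GETAWAY leverage context and R-index autocorrelations.

The molecular influence matrix is H = M (M^T M)^+ M^T where M holds the
centered Cartesian coordinates; its diagonal ("leverages") measures how
far each atom sits from the molecular centre along the principal axes.
The pseudoinverse keeps planar and linear geometries well defined, where
rank(M) drops to 2 or 1 and the leverages sum accordingly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from ..chem.graph import topological_distances
from ..chem.model import Molecule
from ..errors import DescriptorError

log = logging.getLogger(__name__)

_RANK_TOL = 1e-9


@dataclass(frozen=True)
class GetawayContext:
    """Leverages plus geometric and topological distances for one molecule."""

    leverages: np.ndarray      # h_i, one per included atom
    geometric: np.ndarray      # r_ij in angstrom
    topological: np.ndarray    # d_ij in bonds
    atom_indices: list[int]    # molecule indices of the included atoms
    rank: int                  # rank of the centered coordinate matrix

    @property
    def num_atoms(self) -> int:
        return len(self.atom_indices)


def getaway_context(mol: Molecule, include_hydrogens: bool = True) -> GetawayContext:
    """Build the leverage/distance context all R-indices share."""
    indices = list(range(mol.num_atoms)) if include_hydrogens else mol.heavy_indices()
    coords = mol.coordinates()[indices]
    centered = coords - coords.mean(axis=0)
    sv = np.linalg.svd(centered, compute_uv=False)
    rank = int(np.sum(sv > _RANK_TOL * max(sv.max(initial=0.0), 1.0)))
    if rank == 0:
        raise DescriptorError("all atoms coincident; influence matrix undefined",
                              descriptor="GETAWAY")
    h = np.diag(centered @ np.linalg.pinv(centered.T @ centered) @ centered.T)
    geometric = cdist(coords, coords)
    topo = topological_distances(mol, hydrogen_depleted=not include_hydrogens)
    return GetawayContext(np.asarray(h), geometric, topo, indices, rank)


def getaway_r_autocorrelation(
    ctx: GetawayContext,
    weights: np.ndarray,
    lag: int,
    mode: str = "sum",
) -> float:
    """R-index at ``lag``: sum or max over pairs at that topological distance.

    term(i, j) = sqrt(h_i * h_j) / r_ij * w_i * w_j for d_ij == lag;
    ``mode='sum'`` totals the terms, ``mode='max'`` takes the largest
    (the "+" descriptor variants).  No pairs at the lag
    yields 0.
    """
    if lag < 1:
        raise DescriptorError(f"lag must be >= 1, got {lag}", descriptor="R-index")
    if mode not in ("sum", "max"):
        raise DescriptorError(f"mode must be 'sum' or 'max', got {mode!r}",
                              descriptor="R-index")
    weights = np.asarray(weights, dtype=float)
    if weights.shape != (ctx.num_atoms,):
        raise DescriptorError(
            f"weight vector length {weights.size} != atom count {ctx.num_atoms}",
            descriptor="R-index")
    h, r, d = ctx.leverages, ctx.geometric, ctx.topological
    terms = [
        np.sqrt(h[i] * h[j]) / r[i, j] * weights[i] * weights[j]
        for i in range(ctx.num_atoms)
        for j in range(i + 1, ctx.num_atoms)
        if d[i, j] == lag
    ]
    if not terms:
        log.warning("R-index: no atom pairs at lag %d; returning 0", lag)
        return 0.0
    return float(sum(terms) if mode == "sum" else max(terms))
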