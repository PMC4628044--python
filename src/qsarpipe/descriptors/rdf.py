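"""Radial distribution function descriptor over 3D interatomic distances."""
from __future__ import annotations

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ..chem.model import Molecule
from ..chem.weights import WeightTable, scaled_weights
from ..errors import DescriptorError


def rdf_descriptor(
    mol: Molecule,
    radius: float,
    scheme: str,
    beta: float = 100.0,
    include_hydrogens: bool = True,
    tables: dict[str, WeightTable] | None = None,
) -> float:
    """Smoothed weighted distance histogram evaluated at ``radius`` (angstrom).

    RDF(radius) = sum over atom pairs i<j of
    w_i * w_j * exp(-beta * (radius - r_ij)^2), with carbon-scaled weights.
    ``beta`` (1/angstrom^2) controls the smoothing width.
    """
    if beta <= 0:
        raise DescriptorError(f"beta must be positive, got {beta}", descriptor="RDF")
    if radius <= 0:
        raise DescriptorError(f"radius must be positive, got {radius}", descriptor="RDF")
    indices = list(range(mol.num_atoms)) if include_hydrogens else mol.heavy_indices()
    if len(indices) < 2:
        raise DescriptorError("need at least 2 atoms in the included view",
                              descriptor="RDF")
    coords = mol.coordinates()[indices]
    w = scaled_weights(mol, scheme, tables, indices=indices)
    r = pdist(coords)
    ww = _pair_products(w)
    return float(np.sum(ww * np.exp(-beta * (radius - r) ** 2)))


def _pair_products(w: np.ndarray) -> np.ndarray:
    """w_i * w_j for i<j in the same order scipy's pdist enumerates pairs."""
    return squareform(np.outer(w, w), checks=False)
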