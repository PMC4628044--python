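"""Composition of the seven model descriptors into one named vector."""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ..chem.graph import topological_distances
from ..chem.model import Molecule
from ..chem.weights import WeightTable, default_tables, load_property_tables, scaled_weights
from ..errors import DescriptorError
from .centric import lopping_centric_index
from .esters import count_aromatic_esters
from .getaway import getaway_context, getaway_r_autocorrelation
from .moran import moran_autocorrelation
from .rdf import rdf_descriptor

log = logging.getLogger(__name__)

#: canonical output order, also the delimited-text header
DESCRIPTOR_NAMES = ("R5e+", "nArCOOR", "RDF105m", "MATS7m", "MATS8v", "Lop", "R7m")


@dataclass(frozen=True)
class DescriptorConfig:
    """Parameters the engine exposes; defaults follow common usage."""

    rdf_beta: float = 100.0          # 1/angstrom^2
    rdf_radius: float = 10.5         # angstrom ("105" in the descriptor name)
    include_hydrogens_3d: bool = True  # RDF and GETAWAY views
    property_table_path: str | None = None

    def tables(self) -> dict[str, WeightTable]:
        if self.property_table_path is None:
            return default_tables()
        return load_property_tables(self.property_table_path)


@dataclass
class DescriptorVector:
    """Named descriptor values plus per-entry provenance and warnings."""

    values: dict[str, float]
    provenance: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    compound_id: str = ""

    def __post_init__(self):
        for name in self.values:
            if name not in DESCRIPTOR_NAMES:
                raise DescriptorError(f"unknown descriptor name {name!r}")
            self.provenance.setdefault(name, "computed")
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise DescriptorError(f"non-finite value for {name}")
        if "nArCOOR" in self.values:
            n = self.values["nArCOOR"]
            if n < 0 or n != int(n):
                raise DescriptorError(f"nArCOOR must be a non-negative integer, got {n}")
        if self.values.get("Lop", 0.0) < 0:
            raise DescriptorError("Lop must be non-negative")

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    @classmethod
    def supplied(cls, values: dict[str, float], compound_id: str = "") -> "DescriptorVector":
        """Wrap externally computed values (e.g. a published table row)."""
        return cls(dict(values), {k: "supplied" for k in values},
                   compound_id=compound_id)


def compute_descriptor_vector(
    mol: Molecule,
    config: DescriptorConfig | None = None,
) -> DescriptorVector:
    """Compute all seven model descriptors for one molecule.

    MATS and Lop use the hydrogen-depleted graph; RDF and the GETAWAY
    R-indices include hydrogens unless the config says otherwise.  Lags
    beyond the graph diameter yield 0 and are recorded in ``warnings``.
    """
    config = config or DescriptorConfig()
    tables = config.tables()
    warnings: list[str] = []
    values: dict[str, float] = {}

    def run(name, fn):
        try:
            values[name] = float(fn())
        except DescriptorError:
            raise
        except Exception as exc:  # tag unexpected failures with the descriptor
            raise DescriptorError(str(exc), descriptor=name) from exc

    heavy = mol.heavy_indices()
    heavy_dist = topological_distances(mol, hydrogen_depleted=True)
    diameter = int(heavy_dist.max()) if len(heavy) > 1 else 0

    def moran_or_zero(lag, scheme, name):
        if lag > diameter:
            warnings.append(f"{name}: no atom pairs at lag {lag}; value set to 0")
            return 0.0
        return moran_autocorrelation(mol, lag, scheme, tables)

    ctx = getaway_context(mol, include_hydrogens=config.include_hydrogens_3d)
    w_e = scaled_weights(mol, "e", tables, indices=ctx.atom_indices)
    w_m = scaled_weights(mol, "m", tables, indices=ctx.atom_indices)
    ctx_diameter = int(ctx.topological.max())

    def r_index_or_zero(lag, weights, mode, name):
        if lag > ctx_diameter:
            warnings.append(f"{name}: no atom pairs at lag {lag}; value set to 0")
            return 0.0
        return getaway_r_autocorrelation(ctx, weights, lag, mode)

    run("R5e+", lambda: r_index_or_zero(5, w_e, "max", "R5e+"))
    run("nArCOOR", lambda: count_aromatic_esters(mol))
    run("RDF105m", lambda: rdf_descriptor(
        mol, config.rdf_radius, "m", beta=config.rdf_beta,
        include_hydrogens=config.include_hydrogens_3d, tables=tables))
    run("MATS7m", lambda: moran_or_zero(7, "m", "MATS7m"))
    run("MATS8v", lambda: moran_or_zero(8, "v", "MATS8v"))
    run("Lop", lambda: lopping_centric_index(mol))
    run("R7m", lambda: r_index_or_zero(7, w_m, "sum", "R7m"))

    for msg in warnings:
        log.warning("%s: %s", mol.identifier or "<molecule>", msg)
    return DescriptorVector(values, compound_id=mol.identifier, warnings=warnings)
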