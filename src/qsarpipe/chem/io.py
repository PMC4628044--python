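"""Structure readers/writers (SDF V2000, SMILES, XYZ) and coordinate embedding.

RDKit handles SDF/SMILES parsing, aromaticity perception and 3D embedding;
XYZ files are parsed directly (element + three coordinates per line) with
bonds inferred from covalent radii, since the format carries no
connectivity.
"""
from __future__ import annotations

import itertools

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from ..errors import MoleculeError, ParseError
from .model import KNOWN_ELEMENTS, Atom, Bond, Molecule

RDLogger.DisableLog("rdApp.warning")

# Cordero et al., Dalton Trans. 2008 covalent radii (angstrom); used only
# for XYZ bond perception.
_COVALENT_RADII = {
    "H": 0.31, "B": 0.84, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "Si": 1.11, "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39,
}
_BOND_TOLERANCE = 0.40  # angstrom slack added to the radius sum

_ORDER_FROM_RDKIT = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}
_ORDER_TO_RDKIT = {v: k for k, v in _ORDER_FROM_RDKIT.items()}


def _check_element(symbol: str, context: str) -> str:
    if symbol not in KNOWN_ELEMENTS:
        raise ParseError(f"{context}: unknown element symbol {symbol!r}")
    return symbol


def from_rdkit(rdmol: Chem.Mol, identifier: str = "", conformer: int = -1) -> Molecule:
    """Convert an RDKit molecule (with or without a conformer) to a Molecule."""
    has_coords = rdmol.GetNumConformers() > 0
    conf = rdmol.GetConformer(conformer) if has_coords else None
    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        _check_element(a.GetSymbol(), f"molecule {identifier!r}")
        if conf is not None:
            p = conf.GetAtomPosition(i)
            pos = (p.x, p.y, p.z)
        else:
            pos = (0.0, 0.0, 0.0)
        atoms.append(Atom(a.GetSymbol(), pos, a.GetIsAromatic(), i))
    bonds = [
        Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
             _ORDER_FROM_RDKIT.get(b.GetBondType(), 1.0))
        for b in rdmol.GetBonds()
    ]
    return Molecule(atoms, bonds, identifier, has_coordinates=has_coords)


def to_rdkit(mol: Molecule, with_coordinates: bool | None = None) -> Chem.Mol:
    """Build an RDKit molecule mirroring ``mol`` (used for embedding/writing)."""
    rw = Chem.RWMol()
    for a in mol.atoms:
        atom = Chem.Atom(a.element)
        atom.SetIsAromatic(a.is_aromatic)
        atom.SetNoImplicit(True)
        rw.AddAtom(atom)
    for b in mol.bonds:
        rw.AddBond(b.i, b.j, _ORDER_TO_RDKIT.get(b.order, Chem.BondType.SINGLE))
    out = rw.GetMol()
    Chem.SanitizeMol(out, Chem.SanitizeFlags.SANITIZE_ALL
                     ^ Chem.SanitizeFlags.SANITIZE_ADJUSTHS
                     ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES)
    if with_coordinates is None:
        with_coordinates = mol.has_coordinates
    if with_coordinates:
        conf = Chem.Conformer(mol.num_atoms)
        for i, a in enumerate(mol.atoms):
            conf.SetAtomPosition(i, a.position)
        out.AddConformer(conf, assignId=True)
    return out


# -- readers -----------------------------------------------------------------

def _read_sdf(path: str) -> list[Molecule]:
    supplier = Chem.SDMolSupplier(path, removeHs=False, sanitize=True)
    mols = []
    for idx, rdmol in enumerate(supplier, start=1):
        if rdmol is None:
            raise ParseError(f"{path}: SDF record {idx} could not be parsed")
        name = rdmol.GetProp("_Name").strip() if rdmol.HasProp("_Name") else ""
        mols.append(from_rdkit(rdmol, name or f"mol{idx}"))
    return mols


def _read_smiles(path: str) -> list[Molecule]:
    mols = []
    with open(path) as fh:
        for idx, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            smiles = parts[0]
            name = parts[1].strip() if len(parts) > 1 else f"mol{idx}"
            rdmol = Chem.MolFromSmiles(smiles)
            if rdmol is None:
                raise ParseError(f"{path}: SMILES record {idx} ({smiles!r}) "
                                 "could not be parsed")
            rdmol = Chem.AddHs(rdmol)
            mols.append(from_rdkit(rdmol, name))
    return mols


def _read_xyz(path: str) -> list[Molecule]:
    with open(path) as fh:
        lines = fh.read().splitlines()
    mols, i, rec = [], 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        rec += 1
        try:
            count = int(lines[i].split()[0])
        except (ValueError, IndexError):
            raise ParseError(f"{path}: XYZ record {rec} has a bad count line") from None
        comment = lines[i + 1].strip() if i + 1 < len(lines) else ""
        body = lines[i + 2: i + 2 + count]
        if len(body) < count:
            raise ParseError(f"{path}: XYZ record {rec} is truncated")
        atoms = []
        for k, row in enumerate(body):
            fields = row.split()
            if len(fields) < 4:
                raise ParseError(f"{path}: XYZ record {rec}, atom line {k + 1} "
                                 "needs element + 3 coordinates")
            el = _check_element(fields[0], f"{path}: XYZ record {rec}")
            try:
                xyz = tuple(float(v) for v in fields[1:4])
            except ValueError:
                raise ParseError(f"{path}: XYZ record {rec}, atom line {k + 1} "
                                 "has non-numeric coordinates") from None
            atoms.append(Atom(el, xyz, False, k))
        mols.append(Molecule(atoms, _perceive_bonds(atoms),
                             comment or f"mol{rec}"))
        i += 2 + count
    return mols


def _perceive_bonds(atoms: list[Atom]) -> list[Bond]:
    bonds = []
    for a, b in itertools.combinations(atoms, 2):
        cutoff = _COVALENT_RADII[a.element] + _COVALENT_RADII[b.element] + _BOND_TOLERANCE
        d = np.linalg.norm(np.subtract(a.position, b.position))
        if d <= cutoff:
            bonds.append(Bond(a.index, b.index, 1.0))
    return bonds


_READERS = {"sdf": _read_sdf, "smiles": _read_smiles, "xyz": _read_xyz}


def read_structures(path: str, format: str) -> list[Molecule]:
    """Read all records from ``path`` under the given dialect.

    Formats: ``sdf`` (V2000), ``smiles`` (one record per line, optional
    whitespace-separated identifier) and ``xyz``.  SMILES records come
    back coordinate-free (``has_coordinates`` False) with explicit
    hydrogens added.
    """
    try:
        reader = _READERS[format]
    except KeyError:
        raise ParseError(f"unknown structure format {format!r}; "
                         f"expected one of {sorted(_READERS)}") from None
    try:
        return reader(path)
    except OSError as exc:
        raise ParseError(f"cannot read {path}: {exc}") from exc


# -- embedding & writing -----------------------------------------------------

def embed_coordinates(mol: Molecule, seed: int, max_attempts: int = 10) -> Molecule:
    """Assign deterministic 3D coordinates via distance-geometry embedding.

    The same (structure, seed) pair always yields bitwise-identical
    coordinates.  Raises :class:`MoleculeError` after ``max_attempts``
    failed embedding tries.
    """
    if mol.num_atoms > 1 and not mol.bonds:
        raise MoleculeError(
            f"molecule {mol.identifier!r} has no bonds; cannot embed"
        )
    rdmol = to_rdkit(mol, with_coordinates=False)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed)
    conf_id = AllChem.EmbedMolecule(rdmol, params)
    attempt = 1
    while conf_id < 0 and attempt < max_attempts:
        params.randomSeed = int(seed) + attempt
        params.useRandomCoords = True
        conf_id = AllChem.EmbedMolecule(rdmol, params)
        attempt += 1
    if conf_id < 0:
        raise MoleculeError(
            f"embedding failed for molecule {mol.identifier!r} "
            f"after {attempt} attempts"
        )
    out = from_rdkit(rdmol, mol.identifier)
    out.properties = dict(mol.properties)
    return out


def write_sdf(mols: list[Molecule], path: str) -> None:
    """Write molecules to an SDF V2000 file (coordinates required)."""
    writer = Chem.SDWriter(path)
    writer.SetForceV3000(False)
    try:
        for m in mols:
            rdmol = to_rdkit(m)
            rdmol.SetProp("_Name", m.identifier)
            writer.write(rdmol)
    finally:
        writer.close()
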