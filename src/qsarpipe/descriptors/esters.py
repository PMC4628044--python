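"""Aromatic ester (Ar-COOR) counting on the molecular graph."""
from __future__ import annotations

from ..chem.model import Molecule


def count_aromatic_esters(mol: Molecule) -> int:
    """Number of distinct ester groups whose acyl carbon sits on an aromatic ring.

    An ester group is a carbon with a double bond to one oxygen and a single
    bond to a second oxygen that itself bonds to another carbon
    (C(=O)-O-C).  The group counts as aromatic when the carbonyl carbon is
    bonded to at least one aromatic atom; an aromatic ring on the alkoxy
    side alone does not qualify.  Each group is counted once.
    """
    neighbors: dict[int, list[tuple[int, float]]] = {i: [] for i in range(mol.num_atoms)}
    for b in mol.bonds:
        neighbors[b.i].append((b.j, b.order))
        neighbors[b.j].append((b.i, b.order))

    count = 0
    for atom in mol.atoms:
        if atom.element != "C":
            continue
        nbrs = neighbors[atom.index]
        carbonyl_o = [j for j, order in nbrs
                      if mol.atoms[j].element == "O" and order == 2.0]
        ester_o = [
            j for j, order in nbrs
            if mol.atoms[j].element == "O" and order == 1.0
            and any(mol.atoms[k].element == "C" and k != atom.index
                    for k, _ in neighbors[j])
        ]
        if not carbonyl_o or not ester_o:
            continue
        acyl_aromatic = any(
            mol.atoms[j].is_aromatic
            for j, _ in nbrs
            if j not in carbonyl_o and j not in ester_o
        )
        if acyl_aromatic:
            count += 1
    return count
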