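import numpy as np
import pytest

from qsarpipe.chem.model import Atom, Bond, Molecule
from qsarpipe.chem.weights import WeightTable
from qsarpipe.fixtures import published_fixture
from qsarpipe.synthetic import generate_toy_molecules


def chain_molecule(elements, spacing=1.5, bond_orders=None):
    """A linear chain along x with the given elements."""
    atoms = [Atom(el, (i * spacing, 0.0, 0.0), False, i)
             for i, el in enumerate(elements)]
    orders = bond_orders or [1.0] * (len(elements) - 1)
    bonds = [Bond(i, i + 1, orders[i]) for i in range(len(elements) - 1)]
    return Molecule(atoms, bonds, identifier="chain")


def ring_molecule(n=6, element="C", radius=1.4):
    angles = np.linspace(0, 2 * np.pi, n, endpoint=False)
    atoms = [Atom(element, (radius * np.cos(a), radius * np.sin(a), 0.0), True, i)
             for i, a in enumerate(angles)]
    bonds = [Bond(i, (i + 1) % n, 1.5) for i in range(n)]
    return Molecule(atoms, bonds, identifier="ring")


@pytest.fixture(scope="session")
def fixture():
    return published_fixture()


@pytest.fixture(scope="session")
def toy_molecules():
    return generate_toy_molecules(120, seed=7)


@pytest.fixture
def unit_weight_table():
    """Weight table where every scaled weight is trivially recomputable."""
    values = {"C": 1.0, "N": 2.0, "O": 3.0, "S": 4.0, "F": 5.0, "H": 0.5}
    return {s: WeightTable(s, values, 1.0) for s in ("m", "e", "v")}
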