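"""Synthetic inputs: linear descriptor/activity tables and toy molecules.

Randomness comes from a counter-based Philox generator keyed by a stable
hash of the generating spec plus the user seed, so extending a spec with
new fields never silently shifts existing streams.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .chem.model import Atom, Bond, Molecule
from .errors import QsarPipeError

#: default per-descriptor sampling ranges, mimicking the scales of the
#: real descriptor tables the models consume
DEFAULT_RANGES = {
    "R5e+": (0.02, 0.06),
    "RDF105m": (5.0, 20.0),
    "MATS7m": (-0.1, 0.1),
    "MATS8v": (0.1, 0.4),
    "Lop": (0.5, 1.2),
    "R7m": (0.3, 0.6),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a linear descriptor-activity table."""

    n: int
    coefficients: dict[str, float]        # informative descriptor -> slope
    intercept: float = 0.0
    noise_sigma: float = 0.3
    n_noise: int = 0                      # extra pure-noise descriptors
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    feature_correlation: float = 0.0      # equicorrelation among informative columns

    def __post_init__(self):
        if self.n < 3:
            raise QsarPipeError(f"need n >= 3 rows, got {self.n}")
        if self.noise_sigma < 0:
            raise QsarPipeError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if self.n_noise < 0:
            raise QsarPipeError(f"n_noise must be >= 0, got {self.n_noise}")
        if not -0.99 <= self.feature_correlation <= 0.99:
            raise QsarPipeError("feature_correlation must lie in [-0.99, 0.99]")

    def range_for(self, name: str) -> tuple[float, float]:
        if name in self.ranges:
            return self.ranges[name]
        return DEFAULT_RANGES.get(name, (0.0, 1.0))

    def stable_key(self, seed: int) -> int:
        payload = json.dumps(
            {
                "n": self.n,
                "coefficients": sorted(self.coefficients.items()),
                "intercept": self.intercept,
                "noise_sigma": self.noise_sigma,
                "n_noise": self.n_noise,
                "ranges": sorted((k, list(v)) for k, v in self.ranges.items()),
                "feature_correlation": self.feature_correlation,
            },
            sort_keys=True,
        ).encode()
        digest = hashlib.sha256(payload).digest()
        return int.from_bytes(digest[:8], "big") ^ (int(seed) & 0xFFFFFFFFFFFFFFFF)


def _rng(key: int) -> np.random.Generator:
    return np.random.Generator(np.random.Philox(key=key))


def generate_linear_dataset(
    spec: SyntheticSpec, seed: int
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Sample X uniformly per descriptor range and Y = B0 + sum Bn*Xn + noise.

    Returns the table (descriptor columns + ``pic50`` response) and the
    ground-truth coefficient dict (including ``intercept``).  Identical
    (spec, seed) pairs give identical tables.
    """
    rng = _rng(spec.stable_key(seed))
    columns = {}
    names = list(spec.coefficients)
    rho = spec.feature_correlation
    if rho != 0.0 and len(names) > 1:
        # Gaussian copula with equicorrelation, mapped to uniform marginals
        k = len(names)
        cov = np.full((k, k), rho)
        np.fill_diagonal(cov, 1.0)
        z = rng.multivariate_normal(np.zeros(k), cov, size=spec.n,
                                    method="cholesky")
        u = ndtr(z)
        for col, name in enumerate(names):
            lo, hi = spec.range_for(name)
            columns[name] = lo + (hi - lo) * u[:, col]
    else:
        for name in names:
            lo, hi = spec.range_for(name)
            columns[name] = rng.uniform(lo, hi, size=spec.n)
    for k in range(spec.n_noise):
        columns[f"noise{k + 1}"] = rng.uniform(0.0, 1.0, size=spec.n)
    df = pd.DataFrame(columns)
    y = np.full(spec.n, spec.intercept)
    for name, beta in spec.coefficients.items():
        y = y + beta * df[name].to_numpy()
    if spec.noise_sigma > 0:
        y = y + rng.normal(0.0, spec.noise_sigma, size=spec.n)
    df["pic50"] = y
    df.index = [f"S{i + 1}" for i in range(spec.n)]
    df.index.name = "compound_id"
    truth = dict(spec.coefficients)
    truth["intercept"] = spec.intercept
    return df, truth


#: elements drawable for a vertex of the given degree (single bonds only)
_ELEMENTS_BY_DEGREE = {
    1: ("C", "C", "N", "O", "S", "F"),
    2: ("C", "C", "N", "O", "S"),
    3: ("C", "C", "N"),
    4: ("C",),
}
_BOND_LENGTH = 1.5


def generate_toy_molecules(count: int, seed: int) -> list[Molecule]:
    """Random connected heavy-atom molecules (3-12 atoms) with 3D coordinates.

    Atoms chain off a random spanning tree (each placed ~1.5 angstrom from
    its parent in a random direction); with probability 1/2 one extra edge
    closes a ring.  Elements are drawn per-vertex from those whose valence
    supports the final degree, so structures survive a cheminformatics
    round trip.  Deterministic per seed.
    """
    if count < 1:
        raise QsarPipeError(f"count must be >= 1, got {count}")
    rng = _rng(int(seed) ^ 0x746F796D6F6C)
    molecules = []
    for m in range(count):
        n = int(rng.integers(3, 13))
        positions = np.zeros((n, 3))
        bonds = []
        degree = np.zeros(n, dtype=int)
        for i in range(1, n):
            open_slots = [k for k in range(i) if degree[k] < 4]
            parent = int(rng.choice(open_slots))
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            jitter = rng.uniform(0.9, 1.1)
            positions[i] = positions[parent] + _BOND_LENGTH * jitter * direction
            bonds.append(Bond(parent, i))
            degree[parent] += 1
            degree[i] += 1
        if n >= 4 and rng.random() < 0.5:
            existing = {(b.i, b.j) for b in bonds}
            low = [k for k in range(n) if degree[k] <= 2]
            if len(low) >= 2:
                i, j = sorted(rng.choice(low, size=2, replace=False).tolist())
                if (i, j) not in existing:
                    bonds.append(Bond(i, j))
                    degree[i] += 1
                    degree[j] += 1
        elements = [str(rng.choice(_ELEMENTS_BY_DEGREE[min(int(d), 4)]))
                    for d in degree]
        atoms = [Atom(el, tuple(positions[k]), False, k)
                 for k, el in enumerate(elements)]
        molecules.append(Molecule(atoms, bonds, identifier=f"toy{m + 1}"))
    return molecules
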