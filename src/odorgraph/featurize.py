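"""Coulomb matrices, their normalizations, and the bond-adjacency baseline.

The Coulomb matrix of an n-atom molecule is

    C_ii = 0.5 * Z_i ** 2.4
    C_ij = Z_i * Z_j / |R_i - R_j|      (i != j)

with nuclear charges Z and coordinates R.  The diagonal is a polynomial fit of
free-atom energies; off-diagonals are the internuclear Coulomb repulsion.  The
matrix is a fully connected weighted graph over atoms and is invariant to
rigid motions of the molecule.  Distances are taken in the unit the
coordinates are supplied in (angstroms throughout this package); pass
``bohr=True`` to convert to atomic units first.

Two matrix-wise normalizations tame the spread between diagonal and
off-diagonal magnitudes before message passing: division by the Frobenius norm
and min-max scaling, each guarded by eps = 1e-9.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chem import Molecule

EPSILON = 1e-9
ANGSTROM_PER_BOHR = 0.529177210903


@dataclass
class CoulombMatrix:
    values: np.ndarray
    normalization: str = "raw"  # raw | frobenius | minmax
    epsilon: float = EPSILON

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n, m = self.values.shape
        if n != m:
            raise ValueError("Coulomb matrix must be square")
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("Coulomb matrix must be symmetric")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]


@dataclass
class AdjacencyMatrix:
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if not np.array_equal(self.values, self.values.T):
            raise ValueError("adjacency matrix must be symmetric")
        if np.diagonal(self.values).any():
            raise ValueError("adjacency diagonal must be zero")


def compute_coulomb_matrix(mol: Molecule, bohr: bool = False) -> CoulombMatrix:
    """Raw Coulomb matrix from nuclear charges and pairwise distances."""
    if mol.coordinates is None:
        raise ValueError(f"{mol.id}: coordinates required for the Coulomb matrix")
    z = np.asarray(mol.atomic_numbers, dtype=np.float64)
    coords = mol.coordinates / ANGSTROM_PER_BOHR if bohr else mol.coordinates
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    off = ~np.eye(mol.n_atoms, dtype=bool)
    too_close = off & (dist < 1e-6)
    if too_close.any():
        i, j = np.argwhere(too_close)[0]
        raise ValueError(f"{mol.id}: atoms {i} and {j} are (nearly) coincident")
    values = np.zeros_like(dist)
    values[off] = (z[:, None] * z[None, :])[off] / dist[off]
    np.fill_diagonal(values, 0.5 * z**2.4)
    return CoulombMatrix(values, "raw")


def normalize_frobenius(cm: CoulombMatrix) -> CoulombMatrix:
    """C / (||C||_F + eps); the resulting Frobenius norm is strictly below 1."""
    if cm.normalization != "raw":
        raise ValueError("expected a raw Coulomb matrix")
    norm = np.linalg.norm(cm.values, "fro")
    return CoulombMatrix(cm.values / (norm + cm.epsilon), "frobenius", cm.epsilon)


def normalize_minmax(cm: CoulombMatrix) -> CoulombMatrix:
    """(C - Cmin) / (Cmax - Cmin + eps) over all matrix entries."""
    if cm.normalization != "raw":
        raise ValueError("expected a raw Coulomb matrix")
    cmin, cmax = cm.values.min(), cm.values.max()
    return CoulombMatrix((cm.values - cmin) / (cmax - cmin + cm.epsilon), "minmax", cm.epsilon)


def normalize(cm: CoulombMatrix, kind: str) -> CoulombMatrix:
    if kind == "raw":
        return cm
    if kind == "frobenius":
        return normalize_frobenius(cm)
    if kind == "minmax":
        return normalize_minmax(cm)
    raise ValueError(f"unknown normalization {kind!r}")


def compute_adjacency(mol: Molecule) -> AdjacencyMatrix:
    """Binary bond-connectivity matrix (the conventional GCN graph)."""
    values = np.zeros((mol.n_atoms, mol.n_atoms))
    for i, j, _ in mol.bonds:
        values[i, j] = values[j, i] = 1.0
    return AdjacencyMatrix(values)


def dump_matrix(matrix: np.ndarray, path) -> None:
    """Plain-text dense dump (one row per line), loadable with numpy.loadtxt."""
    np.savetxt(path, np.asarray(matrix), fmt="%.12g")
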