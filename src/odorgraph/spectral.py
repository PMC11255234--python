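"""Graph Laplacians of the Coulomb matrix and their low-frequency spectrum.

For a weight matrix X (Coulomb or adjacency) with degree matrix D,

    L1   = D - X                      (combinatorial)
    L2   = I - D^{-1/2} X D^{-1/2}    (symmetric normalized)
    Lrw  = I - D^{-1} X               (random-walk; the asymmetric variant)

Degrees are off-diagonal row sums: the diagonal of X is zeroed first, which
provably leaves L1 and L2 unchanged and fixes the convention for the
normalized variants.  The p lowest eigenpairs — the smooth eigenfunctions
minimizing the Laplacian quadratic form f'L1f = 1/2 sum_ij X_ij (f_i-f_j)^2 —
give each atom a p x 2 spectral input of (eigenvalue, eigenvector component)
rows, zero-padded when the molecule has fewer than p atoms.

The random-walk Laplacian shares its (real) spectrum with L2 through the
similarity D^{1/2} Lrw D^{-1/2} = L2; its eigenvectors are computed from that
symmetric problem and renormalized, so no complex arithmetic ever appears.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .featurize import AdjacencyMatrix, CoulombMatrix

LAPLACIAN_KINDS = ("raw", "symmetric", "asymmetric")


@dataclass
class SpectralDecomposition:
    kind: str
    laplacian: np.ndarray
    degrees: np.ndarray
    p: int | None = None
    eigenvalues: np.ndarray | None = None
    eigenvectors: np.ndarray | None = None  # n x p, columns are phi_k
    padded: bool = False

    @property
    def n_atoms(self) -> int:
        return self.laplacian.shape[0]


def _as_weights(X) -> np.ndarray:
    if isinstance(X, (CoulombMatrix, AdjacencyMatrix)):
        return np.asarray(X.values, dtype=np.float64)
    return np.asarray(X, dtype=np.float64)


def build_degree(X) -> np.ndarray:
    """Diagonal degree matrix from off-diagonal row sums (diagonal zeroed first)."""
    W = _as_weights(X)
    if W.shape[0] != W.shape[1] or not np.allclose(W, W.T, atol=0):
        raise ValueError("weight matrix must be square symmetric")
    off = W.copy()
    np.fill_diagonal(off, 0.0)
    d = off.sum(axis=1)
    if (d <= 0).any():
        bad = int(np.flatnonzero(d <= 0)[0])
        raise ValueError(f"degenerate degree d_{bad}{bad} = {d[bad]:g} <= 0")
    return np.diag(d)


def build_laplacian(X, kind: str = "raw") -> SpectralDecomposition:
    """L1, L2 or Lrw of the (zero-diagonal) weight matrix."""
    if kind not in LAPLACIAN_KINDS:
        raise ValueError(f"kind must be one of {LAPLACIAN_KINDS}, got {kind!r}")
    W = _as_weights(X)
    if W.shape[0] < 2:
        raise ValueError("Laplacian needs at least 2 atoms")
    d = np.diagonal(build_degree(W)).copy()
    W0 = W.copy()
    np.fill_diagonal(W0, 0.0)
    L1 = np.diag(d) - W0
    if kind == "raw":
        lap = L1
    elif kind == "symmetric":
        inv_sqrt = 1.0 / np.sqrt(d)
        lap = inv_sqrt[:, None] * L1 * inv_sqrt[None, :]
    else:  # random-walk
        lap = L1 / d[:, None]
    return SpectralDecomposition(kind, lap, d)


def _canonicalize_signs(phi: np.ndarray) -> np.ndarray:
    """Flip each eigenvector so its largest-magnitude component is positive."""
    phi = phi.copy()
    for k in range(phi.shape[1]):
        col = phi[:, k]
        amax = np.abs(col).max()
        if amax == 0:
            continue
        idx = int(np.flatnonzero(np.abs(col) >= amax - 1e-12)[0])
        if col[idx] < 0:
            phi[:, k] = -col
    return phi


def eigendecompose(
    dec: SpectralDecomposition, p: int = 20, drop_trivial: bool = False
) -> SpectralDecomposition:
    """Attach the p lowest eigenpairs (ascending, sign-canonicalized, padded).

    The trivial near-zero pair is kept among the p lowest unless
    ``drop_trivial`` is set.
    """
    if p < 1:
        raise ValueError("p must be >= 1")
    if not np.all(np.isfinite(dec.laplacian)):
        raise ValueError("non-finite Laplacian entries")
    n = dec.n_atoms
    if dec.kind == "asymmetric":
        inv_sqrt = 1.0 / np.sqrt(dec.degrees)
        sym = inv_sqrt[:, None] * (dec.laplacian * dec.degrees[:, None]) * inv_sqrt[None, :]
        sym = 0.5 * (sym + sym.T)  # kill roundoff asymmetry
        lam, phi = scipy.linalg.eigh(sym)
        phi = inv_sqrt[:, None] * phi  # right eigenvectors of Lrw
        phi /= np.linalg.norm(phi, axis=0, keepdims=True)
    else:
        lam, phi = scipy.linalg.eigh(0.5 * (dec.laplacian + dec.laplacian.T))
    if drop_trivial:
        lam, phi = lam[1:], phi[:, 1:]
    lam, phi = lam[:p], _canonicalize_signs(phi[:, :p])
    padded = lam.shape[0] < p
    if padded:
        lam = np.pad(lam, (0, p - lam.shape[0]))
        phi = np.pad(phi, ((0, 0), (0, p - phi.shape[1])))
    return SpectralDecomposition(dec.kind, dec.laplacian, dec.degrees, p, lam, phi, padded)


def assemble_atom_inputs(dec: SpectralDecomposition) -> list[np.ndarray]:
    """Per-atom p x 2 inputs: rows are (eigenvalue_k, eigenvector_k[atom])."""
    if dec.eigenvalues is None or dec.eigenvectors is None:
        raise ValueError("decomposition has no eigenpairs; call eigendecompose first")
    return [
        np.column_stack([dec.eigenvalues, dec.eigenvectors[i]])
        for i in range(dec.n_atoms)
    ]


def atom_input_array(dec: SpectralDecomposition) -> np.ndarray:
    """All atoms stacked: (n, p, 2)."""
    return np.stack(assemble_atom_inputs(dec))
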