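"""Residual graph convolutions over the Coulomb matrix with learned
positional encoding, ending in a multilabel odor-descriptor head.

One architecture covers three configurations:

* ``adjacency_gcn``   — bond-adjacency message passing, per-element atom
  embeddings (the conventional GCN baseline);
* ``coulomb_gcn``     — the same network with the normalized Coulomb matrix as
  the (fully connected) graph;
* ``lpe_sym`` / ``lpe_asym`` — additionally replace the initial atom embedding
  with a learned positional encoding (LPE): for each atom, the p lowest
  (eigenvalue, eigenvector-component) pairs of the Coulomb-matrix Laplacian
  (symmetric or random-walk normalized) are linearly mapped to width d, run
  through a small Transformer encoder as a length-p sequence, and sum-pooled.

Each graph-convolution layer is the residual update

    H_l = SELU(X H_{l-1} W_graph) + H_{l-1} W_linear

and the molecule embedding m is the atom-wise sum of the final H, fed to a
logistic layer that emits one probability per descriptor.  Batched molecules
are zero-padded with atom masks; padded atoms contribute nothing to message
passing or pooling.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import spectral
from .autodiff import Tensor
from .chem import Molecule
from .featurize import compute_adjacency, compute_coulomb_matrix, normalize
from .nn import Linear, Module, TransformerEncoderLayer

MAX_Z = 118  # size of the per-element embedding table

MATRIX_SOURCES = ("coulomb-frobenius", "coulomb-minmax", "coulomb-raw", "adjacency")


@dataclass
class ModelConfig:
    o: int  # number of odor descriptors
    p: int = 20  # spectral rows per atom
    d: int = 32  # embedding width
    h: int | None = None  # hidden width (defaults to d)
    n_gcn_layers: int = 3
    lpe_layers: int = 1
    lpe_heads: int = 4
    lpe_ff: int | None = None  # defaults to 2 * d
    init_mode: str = "lpe"  # lpe | random
    matrix_source: str = "coulomb-frobenius"
    laplacian_kind: str = "symmetric"
    drop_trivial_eigenpair: bool = False
    combine_atom_embedding: bool = False  # add per-element embedding to the LPE
    bias: bool = True
    seed: int = 0

    def __post_init__(self):
        self.h = self.h or self.d
        self.lpe_ff = self.lpe_ff or 2 * self.d
        if min(self.o, self.p, self.d, self.h) < 1:
            raise ValueError("o, p, d, h must all be >= 1")
        if self.init_mode not in ("lpe", "random"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.matrix_source not in MATRIX_SOURCES:
            raise ValueError(f"unknown matrix_source {self.matrix_source!r}")
        if self.laplacian_kind not in spectral.LAPLACIAN_KINDS:
            raise ValueError(f"unknown laplacian_kind {self.laplacian_kind!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        return cls(**data)


def preset(name: str, o: int, **overrides) -> ModelConfig:
    """Named configurations: adjacency_gcn, coulomb_gcn, lpe_sym, lpe_asym."""
    table = {
        "adjacency_gcn": dict(init_mode="random", matrix_source="adjacency"),
        "coulomb_gcn": dict(init_mode="random", matrix_source="coulomb-frobenius"),
        "lpe_sym": dict(init_mode="lpe", matrix_source="coulomb-frobenius",
                        laplacian_kind="symmetric", combine_atom_embedding=True),
        "lpe_asym": dict(init_mode="lpe", matrix_source="coulomb-frobenius",
                         laplacian_kind="asymmetric", combine_atom_embedding=True),
    }
    if name not in table:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(table)}")
    return ModelConfig(o=o, **{**table[name], **overrides})


# ---------------------------------------------------------------------------
# Per-molecule features
# ---------------------------------------------------------------------------


@dataclass
class MoleculeFeatures:
    """Model-ready arrays for one molecule."""

    mol_id: str
    X: np.ndarray  # n x n graph weights per matrix_source
    atomic_numbers: np.ndarray  # n
    spectral_inputs: np.ndarray | None  # n x p x 2, LPE mode only

    @property
    def n_atoms(self) -> int:
        return self.X.shape[0]


def featurize_for_model(mol: Molecule, config: ModelConfig) -> MoleculeFeatures:
    if config.matrix_source == "adjacency":
        X = compute_adjacency(mol).values
    else:
        cm = compute_coulomb_matrix(mol)
        X = normalize(cm, config.matrix_source.removeprefix("coulomb-")).values
    lam = None
    if config.init_mode == "lpe":
        raw = compute_coulomb_matrix(mol)
        dec = spectral.build_laplacian(raw, config.laplacian_kind)
        dec = spectral.eigendecompose(dec, config.p, config.drop_trivial_eigenpair)
        lam = spectral.atom_input_array(dec)
    return MoleculeFeatures(mol.id, X, np.asarray(mol.atomic_numbers), lam)


@dataclass
class PaddedBatch:
    X: np.ndarray  # B x n x n
    mask: np.ndarray  # B x n, 1.0 for real atoms
    atomic_numbers: np.ndarray  # B x n (0 on padding)
    spectral_inputs: np.ndarray | None  # B x n x p x 2


def pad_batch(features: list[MoleculeFeatures]) -> PaddedBatch:
    B = len(features)
    n_max = max(f.n_atoms for f in features)
    X = np.zeros((B, n_max, n_max))
    mask = np.zeros((B, n_max))
    zs = np.zeros((B, n_max), dtype=np.int64)
    lam = None
    if features[0].spectral_inputs is not None:
        p = features[0].spectral_inputs.shape[1]
        lam = np.zeros((B, n_max, p, 2))
    for b, f in enumerate(features):
        n = f.n_atoms
        X[b, :n, :n] = f.X
        mask[b, :n] = 1.0
        zs[b, :n] = f.atomic_numbers
        if lam is not None:
            lam[b, :n] = f.spectral_inputs
    return PaddedBatch(X, mask, zs, lam)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


class OdorPredictor(Module):
    """The full network; construct via :func:`init_parameters`."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        d, h, bias = config.d, config.h, config.bias
        if config.init_mode == "lpe":
            self.lpe_w0 = Linear(rng, 2, d, bias)
            self.lpe_transformer = [
                TransformerEncoderLayer(rng, d, config.lpe_heads, config.lpe_ff, bias)
                for _ in range(config.lpe_layers)
            ]
        if config.init_mode == "random" or config.combine_atom_embedding:
            # when combined with the LPE, whose pooled magnitude grows like
            # sqrt(p), the element table starts at that scale so neither
            # signal drowns the other
            scale = np.sqrt(config.p) if config.init_mode == "lpe" else 1.0 / np.sqrt(d)
            self.atom_table = Tensor(
                rng.normal(0.0, 1.0, size=(MAX_Z + 1, d)) * scale,
                requires_grad=True,
            )
        self.w_graph = [Linear(rng, d if l == 0 else h, d, bias)
                        for l in range(config.n_gcn_layers)]
        self.w_linear = [Linear(rng, d if l == 0 else h, d, bias)
                         for l in range(config.n_gcn_layers)]
        self.w_clf = Linear(rng, d, config.o, bias)
        # sum-pooling scales logits with atom count; start the head small so
        # initial probabilities are not saturated
        self.w_clf.weight.data *= 0.01

    # -- pieces ---------------------------------------------------------------

    def lpe_encode(self, spectral_inputs: np.ndarray, mask: np.ndarray | None = None) -> Tensor:
        """(B, n, p, 2) spectral inputs -> (B, n, d) initial atom embeddings.

        Each atom is independent, so only real (unmasked) atoms run through
        the Transformer; padded rows stay exactly zero.
        """
        B, n, p, _ = spectral_inputs.shape
        flat = spectral_inputs.reshape(B * n, p, 2)
        real = np.arange(B * n) if mask is None else np.flatnonzero(mask.reshape(-1))
        x = Tensor(flat[real])
        k = self.lpe_w0(x)
        for layer in self.lpe_transformer:
            k = layer(k)
        e = k.sum(axis=1)  # pool the p spectral rows
        return e.scatter_rows(real, B * n).reshape(B, n, self.config.d)

    def atom_type_embed(self, atomic_numbers: np.ndarray) -> Tensor:
        onehot = np.zeros((*atomic_numbers.shape, MAX_Z + 1))
        np.put_along_axis(onehot, atomic_numbers[..., None], 1.0, axis=-1)
        return Tensor(onehot) @ self.atom_table

    def initial_embedding(self, batch: PaddedBatch) -> Tensor:
        if self.config.init_mode == "lpe":
            h0 = self.lpe_encode(batch.spectral_inputs, batch.mask)
            if self.config.combine_atom_embedding:
                h0 = h0 + self.atom_type_embed(batch.atomic_numbers)
        else:
            h0 = self.atom_type_embed(batch.atomic_numbers)
        return h0 * Tensor(batch.mask[..., None])

    def gcn_layer(self, H: Tensor, X: Tensor, layer: int, mask: Tensor) -> Tensor:
        out = (X @ self.w_graph[layer](H)).selu() + self.w_linear[layer](H)
        out = out * mask
        if not np.all(np.isfinite(out.data)):
            raise FloatingPointError(f"non-finite activations in GCN layer {layer}")
        return out

    # -- full forward ---------------------------------------------------------

    def forward(self, batch: PaddedBatch) -> tuple[Tensor, Tensor]:
        """Return (molecule embeddings m: B x d, probabilities y: B x o)."""
        X = Tensor(batch.X)
        mask = Tensor(batch.mask[..., None])
        H = self.initial_embedding(batch)
        for l in range(self.config.n_gcn_layers):
            H = self.gcn_layer(H, X, l, mask)
        m = H.sum(axis=1)  # sum-pool over atoms
        y = self.w_clf(m).sigmoid()
        return m, y

    def predict(self, features: list[MoleculeFeatures]) -> tuple[np.ndarray, np.ndarray]:
        m, y = self.forward(pad_batch(features))
        return m.data, y.data

    # -- persistence ----------------------------------------------------------

    def save(self, path) -> None:
        """Single-archive checkpoint: config JSON + float64 parameter tensors."""
        path = Path(path)
        buf = io.BytesIO()
        np.savez(buf, **{name: p.data for name, p in self.named_parameters()})
        with zipfile.ZipFile(path, "w", zipfile.ZIP_STORED) as zf:
            zf.writestr("config.json", json.dumps(self.config.to_dict(), indent=2))
            zf.writestr("parameters.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "OdorPredictor":
        with zipfile.ZipFile(Path(path)) as zf:
            config = ModelConfig.from_dict(json.loads(zf.read("config.json")))
            arrays = np.load(io.BytesIO(zf.read("parameters.npz")))
            model = init_parameters(config)
            for name, p in model.named_parameters():
                p.data = arrays[name].copy()
        return model


def init_parameters(config: ModelConfig) -> OdorPredictor:
    """Deterministically initialized network for the given config and seed."""
    return OdorPredictor(config, np.random.default_rng(config.seed))
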