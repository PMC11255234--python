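"""Nearest-neighbor retrieval in the learned odor space.

A trained network's penultimate layer — the sum-pooled molecule embedding m —
places molecules in a d-dimensional space where proximity reflects shared
odor character.  Retrieval is exact top-k by cosine similarity, with
deterministic id tie-breaking.  A Tanimoto comparator over Morgan bit
fingerprints is provided as the conventional structural baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .chem import OdorDataset
from .model import OdorPredictor
from .training import MoleculeFeatures, predict, prepare_features


@dataclass
class EmbeddingIndex:
    ids: list[str]
    vectors: np.ndarray  # m x d
    metric: str = "cosine"

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if len(self.ids) != self.vectors.shape[0]:
            raise ValueError("ids and vectors misaligned")
        if self.metric == "cosine" and not np.linalg.norm(self.vectors, axis=1).all():
            raise ValueError("cosine index contains an all-zero vector")

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "vectors.txt", self.vectors, fmt="%.12g")
        (outdir / "ids.txt").write_text("\n".join(self.ids) + "\n")

    @classmethod
    def load(cls, indir) -> "EmbeddingIndex":
        indir = Path(indir)
        ids = (indir / "ids.txt").read_text().splitlines()
        return cls(ids, np.atleast_2d(np.loadtxt(indir / "vectors.txt")))


def build_index(
    model: OdorPredictor,
    dataset: OdorDataset,
    features: list[MoleculeFeatures] | None = None,
) -> EmbeddingIndex:
    """One penultimate-layer embedding per molecule."""
    feats = features if features is not None else prepare_features(dataset, model.config)
    m, _ = predict(model, feats)
    return EmbeddingIndex([mol.id for mol in dataset.molecules], m)


def nearest_neighbors(
    index: EmbeddingIndex, query_id: str, k: int = 5
) -> list[tuple[str, float]]:
    """Top-k by cosine similarity, query excluded, ties broken by id."""
    if query_id not in index.ids:
        raise KeyError(f"unknown molecule id {query_id!r}")
    if k >= len(index.ids):
        raise ValueError(f"k={k} must be smaller than the index size {len(index.ids)}")
    qi = index.ids.index(query_id)
    q = index.vectors[qi]
    norms = np.linalg.norm(index.vectors, axis=1) * np.linalg.norm(q)
    sims = index.vectors @ q / np.where(norms == 0, 1.0, norms)
    order = sorted(
        (i for i in range(len(index.ids)) if i != qi),
        key=lambda i: (-sims[i], index.ids[i]),
    )
    return [(index.ids[i], float(sims[i])) for i in order[:k]]


def tanimoto_neighbors(
    dataset: OdorDataset, query_id: str, k: int = 5, radius: int = 2, n_bits: int = 2048
) -> list[tuple[str, float]]:
    """Baseline comparator: top-k by Tanimoto over Morgan bit fingerprints."""
    ids = [m.id for m in dataset.molecules]
    if query_id not in ids:
        raise KeyError(f"unknown molecule id {query_id!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    fps = [gen.GetFingerprint(Chem.MolFromSmiles(m.smiles)) for m in dataset.molecules]
    qi = ids.index(query_id)
    sims = np.array(DataStructs.BulkTanimotoSimilarity(fps[qi], fps))
    order = sorted(
        (i for i in range(len(ids)) if i != qi), key=lambda i: (-sims[i], ids[i])
    )
    return [(ids[i], float(sims[i])) for i in order[:k]]


def neighbor_label_overlap(
    dataset: OdorDataset, query_idx: int, neighbor_indices
) -> float:
    """Mean Jaccard overlap between a query's descriptor set and its neighbors'."""
    q = dataset.labels[query_idx].astype(bool)
    overlaps = []
    for j in neighbor_indices:
        nb = dataset.labels[j].astype(bool)
        union = (q | nb).sum()
        overlaps.append((q & nb).sum() / union if union else 0.0)
    return float(np.mean(overlaps))
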