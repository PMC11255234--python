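"""Weighted multilabel loss, the training loop, and metric evaluation.

The per-descriptor loss couples binary cross-entropy with a logarithmic
regularization term,

    l_i = BCE(y_true_i, y_pred_i) + | log(y_true_i + eps) - log(y_pred_i + eps) |
    l   = (1/o) * sum_i  w_i * l_i,        w_i = 1 - n_pos_i / n_tot,

so rare descriptors (w_i near 1) dominate and the log term punishes confident
probabilities on the wrong side much harder than BCE alone for negatives.
Training is adaptive-moment gradient descent with early stopping on
validation macro-AUROC.  Evaluation reports AUROC, AUPRC, precision, recall,
specificity and accuracy per descriptor and macro-averaged over descriptors
that have at least one positive and one negative in the evaluated slice.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .autodiff import Tensor
from .chem import EmbeddingError, OdorDataset, SplitAssignment, generate_coordinates
from .model import (
    ModelConfig,
    MoleculeFeatures,
    OdorPredictor,
    featurize_for_model,
    init_parameters,
    pad_batch,
)
from .nn import Adam

EPSILON = 1e-9


# ---------------------------------------------------------------------------
# Loss
# ---------------------------------------------------------------------------


@dataclass
class LossSpec:
    weights: np.ndarray
    epsilon: float = EPSILON
    log_term: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def loss_tensor(y_pred: Tensor, y_true: np.ndarray, spec: LossSpec) -> Tensor:
    """Differentiable batch loss: descriptor-weighted mean, then batch mean."""
    y_true = np.asarray(y_true, dtype=np.float64)
    o = y_true.shape[-1]
    w = Tensor(spec.weights)
    yt = Tensor(y_true)
    # guard against float-rounded sigmoid outputs of exactly 0 or 1
    y_safe = y_pred.clip(1e-12, 1.0 - 1e-12)
    bce = -(yt * y_safe.log() + (1.0 - yt) * (1.0 - y_safe).log())
    per_label = bce
    if spec.log_term:
        log_reg = (
            Tensor(np.log(y_true + spec.epsilon)) - (y_pred + spec.epsilon).log()
        ).abs()
        per_label = per_label + log_reg
    weighted = (w * per_label).sum(axis=-1) * (1.0 / o)
    return weighted.mean()


def compute_loss(y_true, y_pred, spec: LossSpec) -> float:
    """Scalar loss for given labels and probabilities (no gradients)."""
    y_true = np.atleast_2d(np.asarray(y_true, dtype=np.float64))
    y_pred_arr = np.atleast_2d(np.asarray(y_pred, dtype=np.float64))
    if np.any(y_pred_arr <= 0.0) or np.any(y_pred_arr >= 1.0):
        raise ValueError("predictions must be strict probabilities in (0, 1)")
    return float(loss_tensor(Tensor(y_pred_arr), y_true, spec).data)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    batch_size: int = 32
    max_epochs: int = 300
    patience: int = 20  # epochs without validation macro-AUROC improvement
    seed: int = 0
    log_term: bool = True

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs, self.patience) <= 0:
            raise ValueError("training hyperparameters must be positive")


def prepare_features(
    dataset: OdorDataset, config: ModelConfig, coord_seed: int = 0
) -> list[MoleculeFeatures]:
    """Featurize every molecule, generating missing 3D coordinates first.

    Molecules whose embedding fails are never silently dropped: the failure
    propagates so the caller can exclude and log them explicitly.
    """
    features = []
    for mol in dataset.molecules:
        if mol.coordinates is None:
            mol = generate_coordinates(mol, seed=coord_seed)
        features.append(featurize_for_model(mol, config))
    return features


def predict(
    model: OdorPredictor,
    features: list[MoleculeFeatures],
    batch_size: int = 64,
) -> tuple[np.ndarray, np.ndarray]:
    """Embeddings (N x d) and probabilities (N x o) for a feature list."""
    ms, ys = [], []
    for start in range(0, len(features), batch_size):
        m, y = model.predict(features[start : start + batch_size])
        ms.append(m)
        ys.append(y)
    return np.concatenate(ms), np.concatenate(ys)


def _macro_auroc(y_true: np.ndarray, y_score: np.ndarray) -> float:
    vals = []
    for i in range(y_true.shape[1]):
        col = y_true[:, i]
        if 0 < col.sum() < len(col):
            vals.append(roc_auc_score(col, y_score[:, i]))
    return float(np.mean(vals)) if vals else float("nan")


def train(
    dataset: OdorDataset,
    split: SplitAssignment,
    model_config: ModelConfig,
    train_config: TrainConfig | None = None,
    features: list[MoleculeFeatures] | None = None,
) -> tuple[OdorPredictor, pd.DataFrame]:
    """Fit the network; return the best-validation checkpoint and the log.

    The log has one row per epoch: train_loss, val_auroc, val_auprc.
    Precomputed ``features`` (aligned with ``dataset.molecules``) may be passed
    to avoid refeaturizing across runs.
    """
    tc = train_config or TrainConfig()
    if features is None:
        features = prepare_features(dataset, model_config)
    rng = np.random.default_rng(tc.seed)

    train_idx = split.indices("train")
    val_idx = split.indices("validation")
    spec = LossSpec(dataset.weights, log_term=tc.log_term)

    model = init_parameters(model_config)
    params = model.parameters()
    opt = Adam(params, lr=tc.learning_rate)
    val_feats = [features[i] for i in val_idx]
    val_labels = dataset.labels[val_idx]

    best_auroc, best_state, best_epoch = -np.inf, None, -1
    rows = []
    for epoch in range(tc.max_epochs):
        order = train_idx.copy()
        rng.shuffle(order)
        losses = []
        for start in range(0, len(order), tc.batch_size):
            idx = order[start : start + tc.batch_size]
            batch = pad_batch([features[i] for i in idx])
            opt.zero_grad()
            _, y = model.forward(batch)
            loss = loss_tensor(y, dataset.labels[idx], spec)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"training diverged at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        _, val_y = predict(model, val_feats)
        val_auroc = _macro_auroc(val_labels, val_y)
        val_auprc = float(
            np.mean(
                [
                    average_precision_score(val_labels[:, i], val_y[:, i])
                    for i in range(val_labels.shape[1])
                    if 0 < val_labels[:, i].sum() < len(val_idx)
                ]
            )
        )
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_auroc": val_auroc,
                "val_auprc": val_auprc,
            }
        )
        if np.isfinite(val_auroc) and val_auroc > best_auroc:
            best_auroc, best_epoch = val_auroc, epoch
            best_state = [p.data.copy() for p in params]
        if epoch - best_epoch >= tc.patience:
            break
    if best_state is not None:
        for p, state in zip(params, best_state):
            p.data = state
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    per_descriptor: pd.DataFrame
    macro: dict[str, float]
    threshold: float
    excluded: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "macro": self.macro,
                "threshold": self.threshold,
                "excluded": self.excluded,
                "per_descriptor": self.per_descriptor.to_dict(orient="records"),
            },
            indent=2,
        )


METRIC_COLUMNS = ("auroc", "auprc", "precision", "recall", "specificity", "accuracy")


def metrics_from_scores(
    y_true: np.ndarray,
    y_score: np.ndarray,
    names: list[str],
    threshold: float = 0.5,
) -> MetricsReport:
    """Six-metric report from label/score matrices (threshold for the counts)."""
    y_true = np.asarray(y_true)
    rows, excluded = [], []
    for i, name in enumerate(names):
        col, score = y_true[:, i], y_score[:, i]
        n_pos = int(col.sum())
        if n_pos == 0 or n_pos == len(col):
            excluded.append(name)
            continue
        pred = (score >= threshold).astype(int)
        tp = int(((pred == 1) & (col == 1)).sum())
        fp = int(((pred == 1) & (col == 0)).sum())
        fn = int(((pred == 0) & (col == 1)).sum())
        tn = int(((pred == 0) & (col == 0)).sum())
        rows.append(
            {
                "descriptor": name,
                "n_pos": n_pos,
                "auroc": roc_auc_score(col, score),
                "auprc": average_precision_score(col, score),
                "precision": tp / (tp + fp) if tp + fp else 0.0,
                "recall": tp / (tp + fn),
                "specificity": tn / (tn + fp),
                "accuracy": (tp + tn) / len(col),
            }
        )
    per = pd.DataFrame(rows)
    macro = {c: float(per[c].mean()) if len(per) else float("nan") for c in METRIC_COLUMNS}
    return MetricsReport(per, macro, threshold, excluded)


def evaluate(
    model: OdorPredictor,
    dataset: OdorDataset,
    indices=None,
    threshold: float = 0.5,
    features: list[MoleculeFeatures] | None = None,
) -> MetricsReport:
    """Evaluate a trained model on a dataset slice."""
    indices = np.arange(dataset.n_tot) if indices is None else np.asarray(indices)
    if len(indices) == 0:
        raise ValueError("empty evaluation slice")
    if features is None:
        sub = dataset.subset(indices)
        feats = prepare_features(sub, model.config)
    else:
        feats = [features[i] for i in indices]
    _, y = predict(model, feats)
    return metrics_from_scores(
        dataset.labels[indices], y, dataset.vocabulary.names, threshold
    )


def shuffle_labels(dataset: OdorDataset, seed: int = 0) -> OdorDataset:
    """Permutation-null control: reassign label rows to random molecules."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(dataset.n_tot)
    return OdorDataset(dataset.molecules, dataset.labels[perm], dataset.vocabulary)
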