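"""Fully connected multi-output cell-type classifier.

A small dense network mapping an expression profile to one score per
cell type.  Two output modes: ``softmax`` with categorical cross-entropy
for single-label gold standards, and ``sigmoid`` with per-type binary
cross-entropy for ontology-propagated multi-label gold standards (the
sigmoid head lets one cell be called as a child type and its parent
simultaneously).  Implemented directly in NumPy: dense layers with ReLU,
Adam updates, one 100-cell chunk per gradient step, and best-epoch
restore on a held-out validation loss.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from ontoannot.corpus import ChunkStore, ExpressionChunk, validation_holdout, DatasetSplit
from ontoannot.ontology import LabelMatrix

logger = logging.getLogger(__name__)

EPS = 1e-12  # score clip before log
SOFTMAX = "softmax"
SIGMOID = "sigmoid"


class ConfigError(ValueError):
    pass


@dataclass
class ModelConfig:
    """Architecture and optimization settings.

    Defaults follow the reference configuration: three hidden layers of
    256/128/64 ReLU units, Adam with learning rate 3e-5, β1 = 0.9,
    β2 = 0.999, 20 epochs, 100-cell batches.  ``hidden_widths``
    (512, 256, 128, 64) gives the deeper alternative architecture.
    """

    input_dim: int
    output_dim: int
    hidden_widths: tuple[int, ...] = (256, 128, 64)
    output_activation: str = SOFTMAX
    learning_rate: float = 3e-5
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    epochs: int = 20
    batch_size: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.output_activation not in (SOFTMAX, SIGMOID):
            raise ConfigError(f"unknown output activation {self.output_activation!r}")
        if any(w <= 0 for w in self.hidden_widths):
            raise ConfigError("hidden widths must be positive")
        if self.input_dim <= 0 or self.output_dim <= 0:
            raise ConfigError("input_dim and output_dim must be positive")


# ---------------------------------------------------------------------------
# losses

def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, EPS, 1.0)


def cross_entropy_loss(y, p) -> float:
    """Categorical cross-entropy −Σ_c y_c·ln(p_c) for one cell.

    ``y`` is a binary indicator row over types, ``p`` a softmax score
    row; scores are clipped to [1e-12, 1] before the log.
    """
    y = np.asarray(y, dtype=np.float64)
    p = _clip(np.asarray(p, dtype=np.float64))
    return float(-(y * np.log(p)).sum())


def binary_cross_entropy_loss(y, p) -> float:
    """Per-type binary cross-entropy summed over types for one cell.

    −Σ_c [y_c·ln(p_c) + (1−y_c)·ln(1−p_c)], with the same clipping as
    :func:`cross_entropy_loss` applied to both p and 1−p.
    """
    y = np.asarray(y, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    return float(-(y * np.log(_clip(p)) + (1.0 - y) * np.log(_clip(1.0 - p))).sum())


def _batch_loss(Y: np.ndarray, P: np.ndarray, activation: str) -> float:
    """Mean per-cell loss over a batch."""
    Y = Y.astype(np.float64)
    P = P.astype(np.float64)
    if activation == SOFTMAX:
        per_cell = -(Y * np.log(_clip(P))).sum(axis=1)
    else:
        per_cell = -(Y * np.log(_clip(P)) + (1 - Y) * np.log(_clip(1 - P))).sum(axis=1)
    return float(per_cell.mean())


# ---------------------------------------------------------------------------
# network internals

def _init_weights(config: ModelConfig, rng: np.random.Generator):
    """Variance-scaled uniform initialization, seeded."""
    dims = [config.input_dim, *config.hidden_widths, config.output_dim]
    params = []
    for fan_in, fan_out in zip(dims[:-1], dims[1:]):
        bound = np.sqrt(6.0 / (fan_in + fan_out))
        W = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(np.float32)
        b = np.zeros(fan_out, dtype=np.float32)
        params.append([W, b])
    return params


def _forward(params, X: np.ndarray, activation: str):
    """Return (activations list, scores)."""
    acts = [X]
    h = X
    for W, b in params[:-1]:
        h = np.maximum(h @ W + b, 0.0)
        acts.append(h)
    W, b = params[-1]
    z = h @ W + b
    if activation == SOFTMAX:
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        scores = e / e.sum(axis=1, keepdims=True)
    else:
        scores = 1.0 / (1.0 + np.exp(-z))
    return acts, scores


def _backward(params, acts, scores, Y):
    """Gradients of the mean per-cell loss.

    For softmax + categorical CE and sigmoid + summed BCE alike the
    output-layer gradient is (scores − Y) / batch.
    """
    n = Y.shape[0]
    grads = [None] * len(params)
    delta = (scores - Y).astype(np.float32) / np.float32(n)
    for li in range(len(params) - 1, -1, -1):
        W, _ = params[li]
        grads[li] = [acts[li].T @ delta, delta.sum(axis=0)]
        if li > 0:
            delta = (delta @ W.T) * (acts[li] > 0)
    return grads


class _Adam:
    def __init__(self, params, lr: float, beta1: float, beta2: float, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [[np.zeros_like(a) for a in p] for p in params]
        self.v = [[np.zeros_like(a) for a in p] for p in params]

    def step(self, params, grads):
        self.t += 1
        c1 = 1.0 - self.b1**self.t
        c2 = 1.0 - self.b2**self.t
        for p, g, m, v in zip(params, grads, self.m, self.v):
            for k in range(len(p)):
                m[k] = self.b1 * m[k] + (1 - self.b1) * g[k]
                v[k] = self.b2 * v[k] + (1 - self.b2) * g[k] ** 2
                p[k] = p[k] - self.lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + self.eps)


# ---------------------------------------------------------------------------
# public model objects

@dataclass
class TrainedModel:
    """A trained network: the best epoch's weights plus its training trace."""

    config: ModelConfig
    params: list            # [[W, b], ...] of the best epoch
    best_epoch: int         # 1-based epoch whose weights these are
    training_log: pd.DataFrame  # columns epoch, train_loss, val_loss
    type_ids: list[str]
    gene_vocab: list[str] | None = None

    def save(self, path) -> None:
        """Write a portable model archive directory."""
        d = Path(path)
        d.mkdir(parents=True, exist_ok=True)
        cfg = asdict(self.config)
        cfg["hidden_widths"] = list(cfg["hidden_widths"])
        cfg["best_epoch"] = self.best_epoch
        (d / "config.yaml").write_text(yaml.safe_dump(cfg))
        arrays = {}
        for i, (W, b) in enumerate(self.params):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(d / "weights.npz", **arrays)
        pd.Series(self.type_ids).to_csv(d / "type_ids.tsv", sep="\t", index=False, header=False)
        if self.gene_vocab is not None:
            pd.Series(self.gene_vocab).to_csv(d / "gene_vocab.tsv", sep="\t", index=False, header=False)
        self.training_log.to_csv(d / "training_log.tsv", sep="\t", index=False)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        d = Path(path)
        cfg = yaml.safe_load((d / "config.yaml").read_text())
        best_epoch = cfg.pop("best_epoch")
        cfg["hidden_widths"] = tuple(cfg["hidden_widths"])
        config = ModelConfig(**cfg)
        with np.load(d / "weights.npz") as z:
            n_layers = len([k for k in z.files if k.startswith("W")])
            params = [[z[f"W{i}"], z[f"b{i}"]] for i in range(n_layers)]
        type_ids = pd.read_csv(d / "type_ids.tsv", sep="\t", header=None)[0].astype(str).tolist()
        vocab = None
        if (d / "gene_vocab.tsv").exists():
            vocab = pd.read_csv(d / "gene_vocab.tsv", sep="\t", header=None)[0].astype(str).tolist()
        log = pd.read_csv(d / "training_log.tsv", sep="\t")
        return cls(config, params, best_epoch, log, type_ids, vocab)


@dataclass
class ScoreMatrix:
    """Cells × types prediction scores in [0, 1]."""

    cell_ids: list[str]
    type_ids: list[str]
    scores: np.ndarray
    mode: str  # softmax | sigmoid

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.shape != (len(self.cell_ids), len(self.type_ids)):
            raise ValueError("score matrix shape mismatch")


# ---------------------------------------------------------------------------
# training and prediction

def _label_rows(labels: LabelMatrix, cell_ids: Sequence[str], row_of: dict) -> np.ndarray:
    return labels.values[[row_of[c] for c in cell_ids]].astype(np.float32)


def train(
    store: ChunkStore,
    labels: LabelMatrix,
    split: DatasetSplit,
    config: ModelConfig,
    val_fraction: float = 0.1,
) -> TrainedModel:
    """Train on the split's training datasets, restoring the best epoch.

    Chunks of the training datasets are visited in a freshly shuffled
    order each epoch (one Adam step per chunk); a chunk-level validation
    holdout is scored after every epoch and the returned model carries
    the weights of the epoch with minimal validation loss (earliest on
    ties).  Fully reproducible given ``config.seed``.
    """
    train_idx_all = store.indices_for(split.train_datasets)
    return train_on_chunks(store, labels, train_idx_all, config, val_fraction)


def train_on_chunks(
    store: ChunkStore,
    labels: LabelMatrix,
    chunk_indices: Sequence[int],
    config: ModelConfig,
    val_fraction: float = 0.1,
) -> TrainedModel:
    """Train on an explicit set of chunks (cross-cell splits use this)."""
    if config.epochs < 1:
        raise ConfigError("epochs must be >= 1 (no epoch to select otherwise)")
    expected = SOFTMAX if labels.mode == "raw" else SIGMOID
    if config.output_activation != expected:
        raise ConfigError(
            f"label mode {labels.mode!r} requires {expected} output, "
            f"config has {config.output_activation!r}"
        )
    train_idx_all = list(chunk_indices)
    if not train_idx_all:
        raise ConfigError("training set is empty")
    train_idx, val_idx = validation_holdout(train_idx_all, val_fraction, seed=config.seed)
    if not train_idx:
        raise ConfigError("validation holdout consumed all training chunks")

    row_of = {c: i for i, c in enumerate(labels.cell_ids)}
    rng = np.random.default_rng(config.seed)
    params = _init_weights(config, rng)
    opt = _Adam(params, config.learning_rate, config.adam_beta1, config.adam_beta2)

    # chunks are small; cache them in memory for the epoch loop
    train_chunks = [store.load(i) for i in train_idx]
    val_chunks = [store.load(i) for i in val_idx]
    train_Y = [_label_rows(labels, ch.cell_ids, row_of) for ch in train_chunks]
    val_Y = [_label_rows(labels, ch.cell_ids, row_of) for ch in val_chunks]

    log_rows = []
    best = (np.inf, -1, None)  # (val_loss, epoch, params copy)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(len(train_chunks))
        epoch_loss = 0.0
        n_cells = 0
        for ci in order:
            X, Y = train_chunks[ci].matrix, train_Y[ci]
            acts, scores = _forward(params, X, config.output_activation)
            epoch_loss += _batch_loss(Y, scores, config.output_activation) * X.shape[0]
            n_cells += X.shape[0]
            opt.step(params, _backward(params, acts, scores, Y))
        train_loss = epoch_loss / n_cells
        if val_chunks:
            vloss = 0.0
            vn = 0
            for ch, Y in zip(val_chunks, val_Y):
                _, scores = _forward(params, ch.matrix, config.output_activation)
                vloss += _batch_loss(Y, scores, config.output_activation) * ch.n_cells
                vn += ch.n_cells
            val_loss = vloss / vn
        else:
            val_loss = np.nan
        log_rows.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        criterion = val_loss if val_chunks else -epoch  # no holdout: keep last epoch
        if criterion < best[0]:
            best = (criterion, epoch, copy.deepcopy(params))
    _, best_epoch, best_params = best
    logger.info("training done: best epoch %d of %d", best_epoch, config.epochs)
    return TrainedModel(
        config=config,
        params=best_params,
        best_epoch=best_epoch,
        training_log=pd.DataFrame(log_rows),
        type_ids=list(labels.type_ids),
    )


def predict_scores(model: TrainedModel, chunks: Iterable[ExpressionChunk]) -> ScoreMatrix:
    """Score every cell of the given chunks with the trained network."""
    cell_ids: list[str] = []
    blocks = []
    for ch in chunks:
        if ch.matrix.shape[1] != model.config.input_dim:
            raise ValueError(
                f"chunk has {ch.matrix.shape[1]} genes, model expects {model.config.input_dim}"
            )
        _, scores = _forward(model.params, ch.matrix, model.config.output_activation)
        blocks.append(scores)
        cell_ids.extend(ch.cell_ids)
    if not blocks:
        scores = np.zeros((0, model.config.output_dim))
    else:
        scores = np.vstack(blocks)
    return ScoreMatrix(cell_ids, list(model.type_ids), scores, mode=model.config.output_activation)
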