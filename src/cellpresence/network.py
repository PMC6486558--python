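"""The fully connected presence/absence cell-type classifier.

Architecture: the binary gene-presence vector feeds a dense hidden layer of
200 rectified units, then one of 100, with dropout (rate 0.4) after each
hidden layer to control over-fitting; the output layer is a softmax over the
cell-type catalog (K known types plus Unknown).  Training minimizes
class-weighted categorical cross-entropy by mini-batch stochastic gradient
descent (batch size 1024) with momentum, holding out 20% of the training
cells (stratified by type) for validation and stopping early when the
validation loss stops improving, restoring the best-epoch weights.

The implementation is plain numpy: forward, backward and the update rule
are explicit, which is what makes the continual-learning protocols in
:mod:`cellpresence.continual` (bit-exact layer freezing, replay passes
interleaved between epochs, output-layer widening) straightforward to state
and to test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.model_selection import train_test_split

from .io import DataError, GeneSpace
from .preprocess import BinaryProfileMatrix, CellTypeCatalog


@dataclass
class NetworkConfig:
    input_size: int
    hidden_sizes: tuple[int, ...] = (200, 100)
    dropout_rate: float = 0.4

    def __post_init__(self) -> None:
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if any(h < 1 for h in self.hidden_sizes):
            raise ValueError("hidden sizes must be >= 1")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.input_size < 1:
            raise ValueError("input_size must be >= 1")


@dataclass
class TrainConfig:
    batch_size: int = 1024
    validation_fraction: float = 0.2
    max_epochs: int = 30
    patience: int = 3
    learning_rate: float = 0.01
    momentum: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must be in (0, 1)")
        if self.batch_size < 1 or self.patience < 1:
            raise ValueError("batch_size and patience must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class TrainingHistory:
    """Per-epoch training/validation loss and accuracy records."""

    epochs: list[dict] = field(default_factory=list)

    def append(self, **record) -> None:
        self.epochs.append(record)

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    def final(self) -> dict:
        return self.epochs[-1] if self.epochs else {}

    def to_dict(self) -> dict:
        return {"epochs": self.epochs}


@dataclass
class ClassifierModel:
    """Network weights plus everything needed to apply them to new data."""

    config: NetworkConfig
    weights: list[tuple[np.ndarray, np.ndarray]]
    catalog: CellTypeCatalog
    gene_space: GeneSpace
    version: str = "v1"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes = (self.config.input_size, *self.config.hidden_sizes, self.catalog.n_outputs)
        for i, (W, b) in enumerate(self.weights):
            if W.shape != (sizes[i], sizes[i + 1]) or b.shape != (sizes[i + 1],):
                raise DataError(
                    f"layer {i} weight shapes {W.shape}/{b.shape} inconsistent "
                    f"with architecture {sizes}"
                )
        if self.config.input_size != self.gene_space.size:
            raise DataError("input_size does not match gene-space size")

    def copy_weights(self) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(W.copy(), b.copy()) for W, b in self.weights]


def _init_layer(rng: np.random.Generator, fan_in: int, fan_out: int):
    # fan-in scaled uniform (He-style, suits rectifier units)
    limit = np.sqrt(6.0 / fan_in)
    W = rng.uniform(-limit, limit, size=(fan_in, fan_out))
    b = np.zeros(fan_out)
    return W, b


def init_model(
    cfg: NetworkConfig,
    catalog: CellTypeCatalog,
    gene_space: GeneSpace,
    seed: int = 0,
    version: str = "v1",
) -> ClassifierModel:
    """Initialize a classifier with fan-in-scaled uniform weights and zero biases."""
    if cfg.input_size != gene_space.size:
        raise DataError("input_size must equal gene-space size")
    rng = np.random.default_rng(seed)
    sizes = (cfg.input_size, *cfg.hidden_sizes, catalog.n_outputs)
    weights = [_init_layer(rng, sizes[i], sizes[i + 1]) for i in range(len(sizes) - 1)]
    return ClassifierModel(
        config=cfg, weights=weights, catalog=catalog, gene_space=gene_space, version=version
    )


def _forward(weights, X, dropout_rate=0.0, rng=None):
    """Forward pass; returns (activations per layer incl. input, probabilities,
    dropout masks). Dropout is inverted (scaled at train time) and applied only
    when an ``rng`` is supplied."""
    acts = [X]
    masks = []
    h = X
    n_layers = len(weights)
    for i, (W, b) in enumerate(weights):
        z = h @ W + b
        if i < n_layers - 1:
            h = np.maximum(z, 0.0)
            if rng is not None and dropout_rate > 0:
                mask = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
                h = h * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(h)
        else:
            z -= z.max(axis=1, keepdims=True)
            ez = np.exp(z)
            probs = ez / ez.sum(axis=1, keepdims=True)
    return acts, probs, masks


def _weighted_ce(probs, y, sample_w):
    p = np.clip(probs[np.arange(len(y)), y], 1e-12, None)
    return float(np.sum(sample_w * -np.log(p)) / np.sum(sample_w))


class _SGDState:
    """Momentum buffers plus the update rule, honouring frozen layers."""

    def __init__(self, weights, lr, momentum, frozen_layers=()):
        self.lr = lr
        self.momentum = momentum
        self.frozen = set(frozen_layers)
        self.vel = [(np.zeros_like(W), np.zeros_like(b)) for W, b in weights]

    def step(self, weights, grads):
        for i, ((W, b), (gW, gb), (vW, vb)) in enumerate(zip(weights, grads, self.vel)):
            if i in self.frozen:
                continue
            vW *= self.momentum
            vW -= self.lr * gW
            vb *= self.momentum
            vb -= self.lr * gb
            W += vW
            b += vb


def _batch_update(weights, X, y, sample_w, dropout_rate, rng, sgd: _SGDState):
    """One mini-batch: forward with dropout, backprop, SGD step."""
    acts, probs, masks = _forward(weights, X, dropout_rate, rng)
    n = len(y)
    w_sum = np.sum(sample_w)
    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta *= (sample_w / w_sum)[:, None]

    grads = [None] * len(weights)
    for i in range(len(weights) - 1, -1, -1):
        W, _ = weights[i]
        gW = acts[i].T @ delta
        gb = delta.sum(axis=0)
        grads[i] = (gW, gb)
        if i > 0:
            delta = delta @ W.T
            if masks[i - 1] is not None:
                delta *= masks[i - 1]
            delta *= acts[i] > 0
    sgd.step(weights, grads)


def _evaluate(weights, X, y, sample_w):
    _, probs, _ = _forward(weights, X)
    loss = _weighted_ce(probs, y, sample_w)
    acc = float(np.mean(probs.argmax(axis=1) == y))
    return loss, acc


def _stratified_split(indices, y, fraction, seed):
    try:
        tr, va = train_test_split(
            indices, test_size=fraction, stratify=y[indices], random_state=seed
        )
    except ValueError:
        warnings.warn(
            "stratified validation split impossible (a class has too few cells); "
            "falling back to unstratified",
            stacklevel=3,
        )
        tr, va = train_test_split(indices, test_size=fraction, random_state=seed)
    return np.sort(tr), np.sort(va)


def train(
    model: ClassifierModel,
    data: BinaryProfileMatrix,
    labels: Sequence[str],
    tcfg: TrainConfig | None = None,
    class_weights: dict[str, float] | None = None,
    *,
    frozen_layers: Sequence[int] = (),
    replay_hook: Callable | None = None,
) -> tuple[ClassifierModel, TrainingHistory]:
    """Fit the classifier by class-weighted mini-batch SGD.

    A stratified ``validation_fraction`` of the cells is held out; after each
    epoch the validation loss decides early stopping (``patience`` epochs
    without improvement), and the best-epoch weights are restored.  Dropout
    is active only inside the mini-batch updates.

    ``frozen_layers`` lists layer indices excluded from the update (used by
    catalog expansion); ``replay_hook(epoch, step_fn)`` is called after each
    epoch with a function applying one mini-batch update, which is how
    review training replays previous cells.  The model is modified in place
    and also returned.
    """
    tcfg = tcfg or TrainConfig()
    labels = list(labels)
    if data.n_cells != len(labels):
        raise DataError(f"{data.n_cells} cells but {len(labels)} labels")
    y = model.catalog.encode(labels)
    present = np.unique(y)
    if len(present) < 2:
        raise DataError("training labels contain a single class; nothing to separate")
    if data.gene_space != model.gene_space:
        raise DataError("data gene space does not match the model")

    cw = class_weights or {}
    idx_of = model.catalog.class_index()
    w_by_class = np.ones(model.catalog.n_outputs)
    for name, w in cw.items():
        if w <= 0:
            raise DataError("class weights must be positive")
        w_by_class[idx_of[name]] = w
    X = data.values.astype(np.float64)
    sample_w = w_by_class[y]

    ss = np.random.SeedSequence(tcfg.seed)
    split_seed, shuffle_seed, dropout_seed = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    ]
    tr_idx, va_idx = _stratified_split(
        np.arange(len(y)), y, tcfg.validation_fraction, split_seed
    )
    shuffle_rng = np.random.default_rng(shuffle_seed)
    dropout_rng = np.random.default_rng(dropout_seed)
    sgd = _SGDState(model.weights, tcfg.learning_rate, tcfg.momentum, frozen_layers)

    history = TrainingHistory()
    best_loss = np.inf
    best_weights = model.copy_weights()
    wait = 0
    for epoch in range(tcfg.max_epochs):
        order = shuffle_rng.permutation(tr_idx)
        for start in range(0, len(order), tcfg.batch_size):
            b = order[start : start + tcfg.batch_size]
            _batch_update(
                model.weights, X[b], y[b], sample_w[b],
                model.config.dropout_rate, dropout_rng, sgd,
            )
        if replay_hook is not None:
            def step_fn(Xb, yb, wb):
                _batch_update(
                    model.weights, Xb, yb, wb,
                    model.config.dropout_rate, dropout_rng, sgd,
                )
            replay_hook(epoch, step_fn)

        tr_loss, tr_acc = _evaluate(model.weights, X[tr_idx], y[tr_idx], sample_w[tr_idx])
        va_loss, va_acc = _evaluate(model.weights, X[va_idx], y[va_idx], sample_w[va_idx])
        history.append(
            epoch=epoch, train_loss=tr_loss, train_accuracy=tr_acc,
            val_loss=va_loss, val_accuracy=va_acc,
        )
        if va_loss < best_loss - 1e-7:
            best_loss = va_loss
            best_weights = model.copy_weights()
            wait = 0
        else:
            wait += 1
            if wait >= tcfg.patience:
                break
    model.weights = best_weights
    model.metadata.setdefault("training_runs", []).append(
        {"n_cells": int(len(y)), "epochs_run": history.n_epochs,
         "best_val_loss": None if not history.epochs else best_loss}
    )
    return model, history


def predict(
    model: ClassifierModel, data: BinaryProfileMatrix
) -> tuple[list[str], np.ndarray]:
    """Assign each cell a catalog type.

    Returns ``(labels, probabilities)`` where each probability row sums to 1
    and the label is the argmax class (ties broken toward the lowest catalog
    index).  Dropout is disabled; prediction is a pure function of the
    weights and the input.
    """
    if data.gene_space != model.gene_space:
        raise DataError("data gene space does not match the model; align first")
    X = data.values.astype(np.float64)
    _, probs, _ = _forward(model.weights, X)
    classes = model.catalog.classes
    labels = [classes[i] for i in probs.argmax(axis=1)]
    return labels, probs
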