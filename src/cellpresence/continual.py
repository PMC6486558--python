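"""Model upgrade protocols: online optimization and catalog expansion.

Two upgrade paths are supported, both continuing from the current weights
rather than retraining from scratch:

* **Online update** — feed new training cells (labels within the existing
  catalog) through the normal SGD loop.  To counter catastrophic forgetting,
  *review training* replays a fresh random sample of cells from the retained
  previous training pool (default 4000) after each epoch on the new data.
* **Catalog expansion** — add new cell types.  The first hidden layer is
  frozen (its learned feature transform is reused bit-exactly); the output
  layer is widened with freshly initialized rows for the new types, which
  are inserted before the terminal Unknown class; the second hidden layer
  and the output layer then train on the new data, with review training as
  above.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import DataError
from .network import (
    ClassifierModel,
    TrainConfig,
    TrainingHistory,
    _init_layer,
    train,
)
from .preprocess import BinaryProfileMatrix


@dataclass
class ReviewPolicy:
    """How many previous-training cells to replay after each epoch.

    ``review_size=0`` disables review training.  Sampling is without
    replacement within one epoch and reproducible from ``seed``.
    """

    review_size: int = 4000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.review_size < 0:
            raise ValueError("review_size must be >= 0")


def _make_replay_hook(
    model: ClassifierModel,
    pool: BinaryProfileMatrix,
    pool_labels: Sequence[str],
    policy: ReviewPolicy,
    tcfg: TrainConfig,
    class_weights: dict[str, float] | None,
):
    y_pool = model.catalog.encode(list(pool_labels))
    X_pool = pool.values.astype(np.float64)
    idx_of = model.catalog.class_index()
    w_by_class = np.ones(model.catalog.n_outputs)
    for name, w in (class_weights or {}).items():
        w_by_class[idx_of[name]] = w
    w_pool = w_by_class[y_pool]
    size = min(policy.review_size, pool.n_cells)
    if size < policy.review_size:
        warnings.warn(
            f"review_size {policy.review_size} exceeds retained pool "
            f"({pool.n_cells} cells); replaying the whole pool",
            stacklevel=3,
        )
    rng = np.random.default_rng(policy.seed)

    def hook(epoch: int, step_fn) -> None:
        sample = rng.choice(pool.n_cells, size=size, replace=False)
        for start in range(0, size, tcfg.batch_size):
            b = sample[start : start + tcfg.batch_size]
            step_fn(X_pool[b], y_pool[b], w_pool[b])

    return hook


def online_update(
    model: ClassifierModel,
    new_data: BinaryProfileMatrix,
    new_labels: Sequence[str],
    tcfg: TrainConfig | None = None,
    policy: ReviewPolicy | None = None,
    replay_pool: tuple[BinaryProfileMatrix, Sequence[str]] | None = None,
    class_weights: dict[str, float] | None = None,
) -> tuple[ClassifierModel, TrainingHistory]:
    """Continue training an existing model on new data (same catalog).

    Parameters continue from their current values; after each epoch of
    mini-batches over the new data, one review pass over freshly sampled
    previous-pool cells is applied (see :class:`ReviewPolicy`).  All layers
    train.  Labels outside the catalog are an error — use
    :func:`expand_catalog` to add types.
    """
    tcfg = tcfg or TrainConfig()
    policy = policy or ReviewPolicy()
    if new_data.n_cells == 0:
        raise DataError("new_data is empty")
    known = set(model.catalog.classes)
    outside = sorted(set(new_labels) - known)
    if outside:
        raise DataError(
            f"labels {outside} are not in the catalog; use expand_catalog to add types"
        )

    hook = None
    if policy.review_size > 0:
        if replay_pool is None:
            warnings.warn(
                "no retained previous-training pool available; review training skipped",
                stacklevel=2,
            )
        else:
            hook = _make_replay_hook(
                model, replay_pool[0], list(replay_pool[1]), policy, tcfg, class_weights
            )
    return train(
        model, new_data, list(new_labels), tcfg, class_weights, replay_hook=hook
    )


def expand_catalog(
    model: ClassifierModel,
    new_types: Sequence[str],
    data: BinaryProfileMatrix,
    labels: Sequence[str],
    tcfg: TrainConfig | None = None,
    policy: ReviewPolicy | None = None,
    replay_pool: tuple[BinaryProfileMatrix, Sequence[str]] | None = None,
    class_weights: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[ClassifierModel, TrainingHistory]:
    """Widen the catalog by ``new_types`` via transfer learning.

    The output layer gains one freshly initialized column per new type
    (existing columns are copied; the Unknown column keeps its terminal
    position); the first hidden layer is frozen so its weights are
    bit-identical before and after the expansion training; the remaining
    layers train on ``data``/``labels`` (which must include examples of
    every new type), with review training over the retained pool.
    """
    new_types = list(new_types)
    if len(set(new_types)) != len(new_types):
        raise DataError("duplicate names in new_types")
    if not new_types:
        return online_update(
            model, data, labels, tcfg, policy, replay_pool, class_weights
        )
    missing = sorted(set(new_types) - set(labels))
    if missing:
        raise DataError(f"no training examples for declared new types: {missing}")

    old_catalog = model.catalog
    new_catalog = old_catalog.expanded(new_types)
    n_new = len(new_types)

    # widen the output layer: copy existing class columns to their new
    # positions, initialize the new-type columns with the init_model scheme
    W_out, b_out = model.weights[-1]
    fan_in = W_out.shape[0]
    rng = np.random.default_rng(seed)
    W_fresh, _ = _init_layer(rng, fan_in, n_new)
    old_idx = old_catalog.class_index()
    new_idx = new_catalog.class_index()
    W_new = np.zeros((fan_in, new_catalog.n_outputs))
    b_new = np.zeros(new_catalog.n_outputs)
    for name, i_old in old_idx.items():
        W_new[:, new_idx[name]] = W_out[:, i_old]
        b_new[new_idx[name]] = b_out[i_old]
    for k, name in enumerate(new_types):
        W_new[:, new_idx[name]] = W_fresh[:, k]

    model.catalog = new_catalog
    model.weights = model.weights[:-1] + [(W_new, b_new)]

    tcfg = tcfg or TrainConfig()
    policy = policy or ReviewPolicy()
    hook = None
    if policy.review_size > 0:
        if replay_pool is None:
            warnings.warn(
                "no retained previous-training pool available; review training skipped",
                stacklevel=2,
            )
        else:
            hook = _make_replay_hook(
                model, replay_pool[0], list(replay_pool[1]), policy, tcfg, class_weights
            )
    model, history = train(
        model, data, list(labels), tcfg, class_weights,
        frozen_layers=(0,), replay_hook=hook,
    )
    model.version = _bump_version(model.version)
    return model, history


def _bump_version(tag: str) -> str:
    """v1 -> v2, v1m -> v2m; anything unparsable gets '+1' appended."""
    import re

    m = re.match(r"^v(\d+)(.*)$", tag)
    if m:
        return f"v{int(m.group(1)) + 1}{m.group(2)}"
    return tag + "+1"
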