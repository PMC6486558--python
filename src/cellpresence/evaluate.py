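"""Concordance, confusion matrices, cross-validation and label transitions.

*Concordance* is the fraction of cells whose predicted type agrees with a
reference annotation; the ``known-only`` scope restricts the denominator to
cells whose reference label is a specific (non-Unknown) type.  Reference
taxonomies named differently from the catalog can be reconciled through an
explicit rename table before comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold

from .io import DataError
from .preprocess import BinaryProfileMatrix, CellTypeCatalog, compute_class_weights


def apply_rename(labels: Sequence[str], rename: Mapping[str, str]) -> list[str]:
    """Translate labels through a user-supplied rename table (exact match only)."""
    return [rename.get(l, l) for l in labels]


def concordance(
    pred: Sequence[str],
    ref: Sequence[str],
    scope: str = "all",
    unknown_label: str = "Unknown",
) -> float:
    """Fraction of cells where prediction equals the reference label."""
    pred, ref = list(pred), list(ref)
    if len(pred) != len(ref):
        raise DataError(f"length mismatch: {len(pred)} predictions vs {len(ref)} references")
    if not pred:
        raise DataError("empty label vectors")
    if scope == "known-only":
        pairs = [(p, r) for p, r in zip(pred, ref) if r != unknown_label]
        if not pairs:
            raise DataError("no cells with known reference labels")
    elif scope == "all":
        pairs = list(zip(pred, ref))
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return sum(p == r for p, r in pairs) / len(pairs)


@dataclass
class ConfusionMatrix:
    classes: list[str]
    counts: np.ndarray  # rows = reference labels, columns = predictions

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        k = len(self.classes)
        if self.counts.shape != (k, k):
            raise DataError("confusion matrix must be square over the class list")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def trace_fraction(self) -> float:
        return float(np.trace(self.counts) / self.total)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    def write_tsv(self, path) -> None:
        self.to_frame().rename_axis("reference").to_csv(path, sep="\t")


def confusion(
    pred: Sequence[str], ref: Sequence[str], catalog: CellTypeCatalog
) -> ConfusionMatrix:
    """Cross-tabulate reference labels (rows) against predictions (columns)."""
    classes = catalog.classes
    ref_idx = catalog.encode(list(ref))
    pred_idx = catalog.encode(list(pred))
    if len(ref_idx) != len(pred_idx):
        raise DataError("length mismatch")
    k = len(classes)
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (ref_idx, pred_idx), 1)
    return ConfusionMatrix(classes=classes, counts=counts)


@dataclass
class TransitionTable:
    """Cross-tabulation of two labelings of the same cells (Sankey export)."""

    from_classes: list[str]
    to_classes: list[str]
    counts: np.ndarray

    def flow(self, from_label: str, to_label: str) -> int:
        return int(
            self.counts[self.from_classes.index(from_label), self.to_classes.index(to_label)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.from_classes, columns=self.to_classes)

    def to_long(self) -> pd.DataFrame:
        """Tidy (from, to, count) rows with zero flows dropped — plotter-ready."""
        df = self.to_frame().rename_axis("from").reset_index().melt(
            id_vars="from", var_name="to", value_name="count"
        )
        return df[df["count"] > 0].reset_index(drop=True)

    def write_tsv(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def transition_table(
    labels_old: Sequence[str], labels_new: Sequence[str]
) -> TransitionTable:
    """Exact cross-tabulation of an old labeling against a new one."""
    labels_old, labels_new = list(labels_old), list(labels_new)
    if len(labels_old) != len(labels_new):
        raise DataError("labelings cover different numbers of cells")
    from_classes = sorted(set(labels_old))
    to_classes = sorted(set(labels_new))
    fi = {c: i for i, c in enumerate(from_classes)}
    ti = {c: i for i, c in enumerate(to_classes)}
    counts = np.zeros((len(from_classes), len(to_classes)), dtype=np.int64)
    for o, n in zip(labels_old, labels_new):
        counts[fi[o], ti[n]] += 1
    return TransitionTable(from_classes=from_classes, to_classes=to_classes, counts=counts)


def kfold_cv(
    data: BinaryProfileMatrix,
    labels: Sequence[str],
    k: int = 10,
    *,
    catalog: CellTypeCatalog | None = None,
    network_config=None,
    train_config=None,
    use_class_weights: bool = True,
    seed: int = 0,
    stratify: bool = True,
) -> dict:
    """k-fold cross-validated concordance.

    Cells are divided into ``k`` disjoint folds of near-equal size
    (stratified by type by default so small types appear in every test
    fold); for each fold a fresh model is trained on the other ``k-1`` and
    concordance is measured on the held-out fold.  Returns per-fold values
    and their mean.
    """
    from .network import NetworkConfig, TrainConfig, init_model, predict, train

    labels = list(labels)
    if k < 2:
        raise DataError("k must be >= 2")
    if data.n_cells != len(labels):
        raise DataError("label count does not match cell count")
    if catalog is None:
        names = sorted(set(labels) - {"Unknown"})
        catalog = CellTypeCatalog(known_types=names)
    y = catalog.encode(labels)
    min_class = int(np.bincount(y, minlength=catalog.n_outputs)[np.unique(y)].min())
    if stratify and min_class < k:
        warnings.warn(
            f"smallest class has {min_class} < k={k} cells; "
            "degrading to unstratified folds",
            stacklevel=2,
        )
        stratify = False
    splitter = (
        StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        if stratify
        else KFold(n_splits=k, shuffle=True, random_state=seed)
    )
    ncfg = network_config or NetworkConfig(input_size=data.gene_space.size)
    base_tcfg = train_config or TrainConfig()

    fold_concordances = []
    fold_sizes = []
    fold_test_indices = []
    arr_labels = np.array(labels)
    for fold, (tr, te) in enumerate(splitter.split(np.zeros(len(y)), y)):
        fold_test_indices.append([int(i) for i in te])
        tcfg = TrainConfig(**{**base_tcfg.__dict__, "seed": base_tcfg.seed + fold})
        cw = (
            compute_class_weights(arr_labels[tr].tolist(), catalog)
            if use_class_weights
            else None
        )
        m = init_model(ncfg, catalog, data.gene_space, seed=seed + 1000 + fold)
        m, _ = train(m, data.subset(tr), arr_labels[tr].tolist(), tcfg, cw)
        pred, _ = predict(m, data.subset(te))
        fold_concordances.append(concordance(pred, arr_labels[te].tolist()))
        fold_sizes.append(len(te))
    return {
        "k": k,
        "fold_concordances": fold_concordances,
        "fold_sizes": fold_sizes,
        "fold_test_indices": fold_test_indices,
        "mean_concordance": float(np.mean(fold_concordances)),
    }
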