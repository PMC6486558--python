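"""Presence/absence feature construction and training-set preparation.

The classifier consumes binary features: a gene is *present* in a cell when
its UMI count is positive and *absent* otherwise.  Any positive count marks
presence — UMI platforms make counts digital, so a single molecule is
evidence of expression, and signal dropouts are tolerated by design the way
dead pixels are tolerated in image recognition.

This module also synthesizes "unknown"-class training profiles by shuffling
gene values within real cells (destroying co-expression structure while
preserving per-cell library complexity) and computes balanced
inverse-frequency class weights so small cell types are not drowned out by
abundant ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import DataError, ExpressionMatrix, GeneSpace

UNKNOWN_LABEL = "Unknown"


@dataclass
class CellTypeCatalog:
    """Ordered known cell types plus the mandatory terminal Unknown class."""

    known_types: list[str]
    unknown_label: str = UNKNOWN_LABEL

    def __post_init__(self) -> None:
        self.known_types = list(self.known_types)
        if len(set(self.known_types)) != len(self.known_types):
            raise DataError("duplicate cell-type names in catalog")
        if self.unknown_label in self.known_types:
            raise DataError(f"{self.unknown_label!r} may not be a known type")

    @property
    def classes(self) -> list[str]:
        """Output order: known types first, Unknown last."""
        return self.known_types + [self.unknown_label]

    @property
    def n_outputs(self) -> int:
        return len(self.known_types) + 1

    def class_index(self) -> dict[str, int]:
        return {c: i for i, c in enumerate(self.classes)}

    def encode(self, labels) -> np.ndarray:
        idx = self.class_index()
        try:
            return np.array([idx[l] for l in labels], dtype=np.int64)
        except KeyError as exc:
            raise DataError(f"label {exc.args[0]!r} not in catalog") from exc

    def expanded(self, new_types) -> "CellTypeCatalog":
        """New catalog with ``new_types`` appended to the known list
        (i.e. inserted before the terminal Unknown class)."""
        new_types = list(new_types)
        clash = set(new_types) & set(self.known_types)
        if clash:
            raise DataError(f"types already in catalog: {sorted(clash)}")
        return CellTypeCatalog(
            known_types=self.known_types + new_types, unknown_label=self.unknown_label
        )


@dataclass
class BinaryProfileMatrix:
    """Cells x genes matrix of {0,1} presence calls, columns in gene-space order."""

    gene_space: GeneSpace
    cells: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.ndim != 2 or self.values.shape != (
            len(self.cells),
            self.gene_space.size,
        ):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cells)} cells x {self.gene_space.size} genes"
            )
        if self.values.size and self.values.max() > 1:
            raise DataError("binary matrix contains values outside {0,1}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def subset(self, mask_or_index) -> "BinaryProfileMatrix":
        idx = np.asarray(mask_or_index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return BinaryProfileMatrix(
            gene_space=self.gene_space,
            cells=[self.cells[i] for i in idx],
            values=self.values[idx],
        )

    def concat(self, other: "BinaryProfileMatrix") -> "BinaryProfileMatrix":
        if other.gene_space != self.gene_space:
            raise DataError("gene spaces differ")
        return BinaryProfileMatrix(
            gene_space=self.gene_space,
            cells=self.cells + other.cells,
            values=np.vstack([self.values, other.values]),
        )


def binarize(m: ExpressionMatrix, gene_space: GeneSpace | None = None) -> BinaryProfileMatrix:
    """Convert UMI counts to presence calls: ``1`` iff count > 0.

    The input is genes x cells (the on-disk convention); the output is
    transposed to cells x genes, the sample-per-row convention the network
    expects.  ``m`` must already be aligned to the model's gene space; pass
    ``gene_space`` to assert that the gene order matches.
    """
    if gene_space is not None and list(m.genes) != list(gene_space.symbols):
        raise DataError("matrix gene order does not match the gene space; align first")
    gs = gene_space or GeneSpace(m.genes)
    values = (m.counts.toarray() > 0).astype(np.uint8).T
    return BinaryProfileMatrix(gene_space=gs, cells=list(m.cells), values=values)


def synthesize_unknown(
    source: BinaryProfileMatrix, n: int, seed: int
) -> BinaryProfileMatrix:
    """Create ``n`` synthetic "unknown" profiles by within-cell shuffling.

    Each synthetic profile is a uniformly random permutation of the gene
    values of one source cell drawn with replacement, so the number of
    present genes (library complexity) is preserved per profile while all
    co-expression structure is destroyed — the profile resembles no real
    cell type and is always labeled Unknown during training.
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if source.n_cells == 0:
        raise DataError("source matrix is empty")
    rng = np.random.default_rng(seed)
    picks = rng.integers(0, source.n_cells, size=n)
    out = np.empty((n, source.gene_space.size), dtype=np.uint8)
    for row, pick in enumerate(picks):
        out[row] = rng.permutation(source.values[pick])
    cells = [f"synthetic_unknown_{i}" for i in range(n)]
    return BinaryProfileMatrix(gene_space=source.gene_space, cells=cells, values=out)


def compute_class_weights(labels, catalog: CellTypeCatalog) -> dict[str, float]:
    """Balanced inverse-frequency class weights.

    ``weight_c = N_total / (n_classes_present * N_c)``, so rare cell types
    contribute as much total loss as abundant ones.  The identity
    ``sum_c weight_c * N_c == N_total`` holds exactly.  Catalog classes with
    no examples are omitted from the result.
    """
    labels = list(labels)
    if not labels:
        raise DataError("empty label list")
    valid = set(catalog.classes)
    counts: dict[str, int] = {}
    for l in labels:
        if l not in valid:
            raise DataError(f"label {l!r} not in catalog")
        counts[l] = counts.get(l, 0) + 1
    n_total = len(labels)
    n_present = len(counts)
    return {c: n_total / (n_present * n) for c, n in counts.items()}
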