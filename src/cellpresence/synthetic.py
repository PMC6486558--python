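"""Synthetic binary single-cell profiles with planted marker structure.

The generator emulates what binarized UMI data looks like to the
classifier: each cell type owns a block of marker genes that are present
with high probability in that type and rarely elsewhere, on top of
uninformative background genes and a global extra-dropout factor that
thins presence calls the way technical dropouts do.  Genes are independent
Bernoulli draws given the type — there is no gene-gene correlation beyond
the type structure — which is sufficient to exercise every pipeline stage
with known ground truth and no downloads.

Benchmarks built on the generator:

* :func:`generate_upgrade_benchmark` — a base catalog plus unseen types
  that appear as Unknown in phase 1 and as specific types in phase 2,
  mirroring a catalog-expansion upgrade.
* :func:`generate_domain_shift_benchmark` — the same catalog observed under
  a shifted presence-probability regime (a platform/batch effect), used to
  probe catastrophic forgetting and review training.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import DataError, GeneSpace
from .preprocess import BinaryProfileMatrix, CellTypeCatalog, synthesize_unknown


@dataclass
class SyntheticConfig:
    """Study conditions for the generator.

    ``p_marker_on``/``p_marker_off`` are marker presence probabilities in
    the owning type and elsewhere; ``dropout_extra`` is an additional global
    zeroing probability applied to every would-be presence call;
    ``presence_offset`` shifts all presence probabilities (clipped to
    [0, 1]) to emulate a platform or batch regime change;
    ``class_size_multipliers`` scales per-type cell counts to create
    imbalance.
    """

    n_types: int = 6
    markers_per_type: int = 40
    n_background_genes: int = 1500
    p_marker_on: float = 0.8
    p_marker_off: float = 0.05
    p_background_on: float = 0.10
    cells_per_type: int = 500
    dropout_extra: float = 0.1
    presence_offset: float = 0.0
    class_size_multipliers: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_types < 1 or self.cells_per_type < 1:
            raise DataError("need at least one type and one cell per type")
        for p in (self.p_marker_on, self.p_marker_off, self.p_background_on,
                  self.dropout_extra):
            if not (0 <= p <= 1):
                raise DataError("probabilities must lie in [0, 1]")
        if self.p_marker_on <= self.p_marker_off:
            raise DataError("p_marker_on must exceed p_marker_off")
        if self.class_size_multipliers is not None and len(
            self.class_size_multipliers
        ) != self.n_types:
            raise DataError("class_size_multipliers must have one entry per type")

    @property
    def n_genes(self) -> int:
        return self.n_types * self.markers_per_type + self.n_background_genes

    def type_names(self) -> list[str]:
        return [f"Type{t + 1:02d}" for t in range(self.n_types)]

    def gene_space(self) -> GeneSpace:
        symbols = []
        for t in range(self.n_types):
            symbols += [f"MK{t + 1:02d}G{i + 1:03d}" for i in range(self.markers_per_type)]
        symbols += [f"BG{i + 1:04d}" for i in range(self.n_background_genes)]
        return GeneSpace(symbols)

    def catalog(self) -> CellTypeCatalog:
        return CellTypeCatalog(known_types=self.type_names())

    def marker_map(self) -> dict[str, list[str]]:
        gs = self.gene_space().symbols
        return {
            name: gs[t * self.markers_per_type : (t + 1) * self.markers_per_type]
            for t, name in enumerate(self.type_names())
        }

    def presence_probabilities(self) -> np.ndarray:
        """(n_types x n_genes) matrix of per-gene presence probabilities."""
        p = np.full((self.n_types, self.n_genes), self.p_background_on)
        n_marker = self.n_types * self.markers_per_type
        p[:, :n_marker] = self.p_marker_off
        for t in range(self.n_types):
            lo = t * self.markers_per_type
            p[t, lo : lo + self.markers_per_type] = self.p_marker_on
        p *= 1.0 - self.dropout_extra
        return np.clip(p + self.presence_offset, 0.0, 1.0)


def generate_labeled_dataset(
    cfg: SyntheticConfig,
) -> tuple[BinaryProfileMatrix, list[str], dict[str, list[str]]]:
    """Draw a labeled binary dataset under ``cfg``.

    Returns the profile matrix (cells grouped by type), the per-cell type
    labels, and the ground-truth map of each type to its planted marker
    genes.  Fully reproducible from ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    probs = cfg.presence_probabilities()
    names = cfg.type_names()
    mult = cfg.class_size_multipliers or (1.0,) * cfg.n_types
    sizes = [max(1, int(round(cfg.cells_per_type * m))) for m in mult]

    blocks, labels, cells = [], [], []
    for t, (name, size) in enumerate(zip(names, sizes)):
        blocks.append((rng.random((size, cfg.n_genes)) < probs[t]).astype(np.uint8))
        labels += [name] * size
        cells += [f"{name}_cell{i + 1:05d}" for i in range(size)]
    matrix = BinaryProfileMatrix(
        gene_space=cfg.gene_space(), cells=cells, values=np.vstack(blocks)
    )
    return matrix, labels, cfg.marker_map()


@dataclass
class UpgradeBenchmark:
    """Datasets for a catalog-expansion experiment over a shared gene space."""

    gene_space: GeneSpace
    base_catalog: CellTypeCatalog
    expanded_catalog: CellTypeCatalog
    new_types: list[str]
    train_base: tuple[BinaryProfileMatrix, list[str]]  # base types + synthetic Unknown
    train_new: tuple[BinaryProfileMatrix, list[str]]  # new types, specific labels
    test_old: tuple[BinaryProfileMatrix, list[str]]  # held-out base-type cells
    test_new_matrix: BinaryProfileMatrix  # held-out new-type cells
    test_new_labels_phase1: list[str]  # all Unknown
    test_new_labels_phase2: list[str]  # specific new types
    marker_map: dict[str, list[str]]


def generate_upgrade_benchmark(
    cfg: SyntheticConfig,
    n_new_types: int = 2,
    seed: int | None = None,
    n_unknown: int | None = None,
) -> UpgradeBenchmark:
    """Build matched phase-1/phase-2 datasets for catalog expansion.

    The gene space covers marker blocks for both the ``cfg.n_types`` base
    types and ``n_new_types`` additional types, so a phase-1 model already
    sees the (mostly silent) new-type markers.  Phase-1 training data holds
    base-type cells plus shuffled synthetic Unknown profiles; the new-type
    cells carry Unknown ground truth in phase 1 and specific labels in
    phase 2.
    """
    if n_new_types < 1:
        raise DataError("n_new_types must be >= 1")
    seed = cfg.seed if seed is None else seed
    full = replace(cfg, n_types=cfg.n_types + n_new_types, seed=seed)
    names = full.type_names()
    base_names, new_names = names[: cfg.n_types], names[cfg.n_types :]

    def draw(type_indices, tag, draw_seed):
        sub_rng = np.random.default_rng(draw_seed)
        probs = full.presence_probabilities()
        blocks, labels, cells = [], [], []
        for t in type_indices:
            size = full.cells_per_type
            blocks.append(
                (sub_rng.random((size, full.n_genes)) < probs[t]).astype(np.uint8)
            )
            labels += [names[t]] * size
            cells += [f"{tag}_{names[t]}_cell{i + 1:05d}" for i in range(size)]
        return (
            BinaryProfileMatrix(
                gene_space=full.gene_space(), cells=cells, values=np.vstack(blocks)
            ),
            labels,
        )

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)]
    base_idx = list(range(cfg.n_types))
    new_idx = list(range(cfg.n_types, cfg.n_types + n_new_types))

    train_base_m, train_base_l = draw(base_idx, "train", seeds[0])
    n_unknown = full.cells_per_type if n_unknown is None else n_unknown
    unknown = synthesize_unknown(train_base_m, n_unknown, seeds[1])
    train_base = (
        train_base_m.concat(unknown),
        train_base_l + ["Unknown"] * n_unknown,
    )
    train_new = draw(new_idx, "trainnew", seeds[2])
    test_old = draw(base_idx, "testold", seeds[3])
    test_new_m, test_new_specific = draw(new_idx, "testnew", seeds[4])

    base_catalog = CellTypeCatalog(known_types=base_names)
    return UpgradeBenchmark(
        gene_space=full.gene_space(),
        base_catalog=base_catalog,
        expanded_catalog=base_catalog.expanded(new_names),
        new_types=new_names,
        train_base=train_base,
        train_new=train_new,
        test_old=test_old,
        test_new_matrix=test_new_m,
        test_new_labels_phase1=["Unknown"] * test_new_m.n_cells,
        test_new_labels_phase2=test_new_specific,
        marker_map=full.marker_map(),
    )


@dataclass
class DomainShiftBenchmark:
    """Same catalog observed under two presence-probability regimes.

    Domain B covers only ``types_in_b`` — updating a whole-catalog model on
    data from a few types is precisely the situation in which the classes
    absent from the new data are forgotten.
    """

    gene_space: GeneSpace
    catalog: CellTypeCatalog
    types_in_b: list[str]
    train_a: tuple[BinaryProfileMatrix, list[str]]
    test_a: tuple[BinaryProfileMatrix, list[str]]
    train_b: tuple[BinaryProfileMatrix, list[str]]
    test_b: tuple[BinaryProfileMatrix, list[str]]


def generate_domain_shift_benchmark(
    cfg: SyntheticConfig,
    offset: float = 0.45,
    seed: int | None = None,
    types_in_b: Sequence[str] | None = None,
) -> DomainShiftBenchmark:
    """Two domains of the same cell types differing by a presence regime.

    Domain A uses ``cfg`` as-is.  Domain B shifts every presence
    probability by ``offset`` (the default +0.45 emulates a much deeper /
    noisier platform in which foreign markers and background genes fire
    frequently) and contains only ``types_in_b`` (default: the last half of
    the catalog, emulating a tissue-restricted follow-up dataset).
    Sequential training A-then-B induces forgetting of domain A — the new
    data actively relabels patterns that look like the old types — which is
    the situation review training is designed to counter.
    """
    seed = cfg.seed if seed is None else seed
    names = cfg.type_names()
    if types_in_b is None:
        types_in_b = names[cfg.n_types // 2 :]
    types_in_b = list(types_in_b)
    unknown_b = sorted(set(types_in_b) - set(names))
    if unknown_b:
        raise DataError(f"types_in_b not in catalog: {unknown_b}")
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    cfg_b = replace(cfg, presence_offset=cfg.presence_offset + offset)

    def dataset(c, s, keep=None):
        m, l, _ = generate_labeled_dataset(replace(c, seed=s))
        if keep is not None:
            mask = np.array([x in keep for x in l])
            m = m.subset(mask)
            l = [x for x in l if x in keep]
        return m, l

    keep = set(types_in_b)
    return DomainShiftBenchmark(
        gene_space=cfg.gene_space(),
        catalog=cfg.catalog(),
        types_in_b=types_in_b,
        train_a=dataset(cfg, seeds[0]),
        test_a=dataset(cfg, seeds[1]),
        train_b=dataset(cfg_b, seeds[2], keep),
        test_b=dataset(cfg_b, seeds[3], keep),
    )
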