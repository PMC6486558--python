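"""Signature-gene discovery by information gain.

For each cell type, every gene's presence/absence pattern is scored by the
reduction in entropy of binary type membership obtained by observing the
gene's status:

    Gain(T; G) = H(T) - sum_j P(G=j) * H(T | G=j),  j in {present, absent}

where T indicates whether a cell belongs to the type (one-vs-rest) and G is
the binarized gene signal.  For two binary variables this equals their
mutual information, computed from a single 2x2 contingency table.  Gains are
reported in bits (base-2 logs); the ranking is invariant to the log base.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import DataError
from .preprocess import BinaryProfileMatrix


@dataclass
class ContingencyTable:
    """2x2 tally: (in-type vs rest) x (gene present vs absent)."""

    n11: int  # in-type, present
    n10: int  # in-type, absent
    n01: int  # out-of-type, present
    n00: int  # out-of-type, absent

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise DataError("contingency counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def contingency(
    data: BinaryProfileMatrix,
    labels: Sequence[str],
    cell_type: str,
    gene: str,
) -> ContingencyTable:
    """Tally one (gene, type) pair over all cells."""
    labels = list(labels)
    if data.n_cells != len(labels):
        raise DataError("label count does not match cell count")
    try:
        j = data.gene_space.index()[gene.strip().upper()]
    except KeyError:
        raise DataError(f"gene {gene!r} not in gene space") from None
    if cell_type not in labels:
        raise DataError(f"type {cell_type!r} absent from labels")
    in_type = np.array([l == cell_type for l in labels])
    present = data.values[:, j].astype(bool)
    return ContingencyTable(
        n11=int(np.sum(in_type & present)),
        n10=int(np.sum(in_type & ~present)),
        n01=int(np.sum(~in_type & present)),
        n00=int(np.sum(~in_type & ~present)),
    )


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in bits; 0*log(0) := 0."""
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def information_gain(t: ContingencyTable) -> float:
    """Entropy reduction of type membership from observing the gene, in bits.

    ``H(T) - P(present) H(T|present) - P(absent) H(T|absent)``; clipped to
    ``>= 0`` against floating-point rounding.
    """
    n = t.total
    if n == 0:
        raise DataError("empty contingency table")
    p_in = (t.n11 + t.n10) / n
    h_type = _entropy(np.array([p_in, 1 - p_in]))
    gain = h_type
    for present_count, absent_count in (((t.n11, t.n01)), ((t.n10, t.n00))):
        nj = present_count + absent_count
        if nj == 0:
            continue
        cond = _entropy(np.array([present_count / nj, absent_count / nj]))
        gain -= (nj / n) * cond
    return max(gain, 0.0)


def _gains_all_genes(values: np.ndarray, in_type: np.ndarray) -> np.ndarray:
    """Vectorized information gain of every gene column against one type mask."""
    n = values.shape[0]
    n_in = int(in_type.sum())
    n11 = in_type.astype(np.int64) @ values  # per-gene in-type presence
    n01 = values.sum(axis=0, dtype=np.int64) - n11
    n10 = n_in - n11
    n00 = (n - n_in) - n01

    def h2(a, b):
        tot = a + b
        with np.errstate(divide="ignore", invalid="ignore"):
            pa = np.where(tot > 0, a / np.maximum(tot, 1), 0.0)
            pb = np.where(tot > 0, b / np.maximum(tot, 1), 0.0)
            ha = np.where(pa > 0, -pa * np.log2(np.maximum(pa, 1e-300)), 0.0)
            hb = np.where(pb > 0, -pb * np.log2(np.maximum(pb, 1e-300)), 0.0)
        return ha + hb

    h_type = h2(np.full_like(n11, n_in, dtype=float), np.full_like(n11, n - n_in, dtype=float))
    n_present = n11 + n01
    n_absent = n10 + n00
    gain = (
        h_type
        - (n_present / n) * h2(n11.astype(float), n01.astype(float))
        - (n_absent / n) * h2(n10.astype(float), n00.astype(float))
    )
    return np.maximum(gain, 0.0)


@dataclass
class SignatureRanking:
    """Genes ranked by information gain for one cell type, best first."""

    cell_type: str
    table: pd.DataFrame  # columns: rank, gene, gain_bits, n11, n10, n01, n00

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    @property
    def gains(self) -> list[float]:
        return list(self.table["gain_bits"])

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def top_signature_genes(
    data: BinaryProfileMatrix,
    labels: Sequence[str],
    cell_type: str,
    n: int = 50,
) -> SignatureRanking:
    """Rank genes for one type by information gain; return the top ``n``.

    Ties are broken lexicographically by gene symbol so the ranking is
    deterministic.  Asking for more genes than exist returns them all with a
    warning.
    """
    labels = list(labels)
    if cell_type not in labels:
        raise DataError(f"type {cell_type!r} absent from labels")
    if data.n_cells != len(labels):
        raise DataError("label count does not match cell count")
    symbols = data.gene_space.symbols
    if n > len(symbols):
        warnings.warn(
            f"requested top {n} of only {len(symbols)} genes; returning all",
            stacklevel=2,
        )
        n = len(symbols)

    in_type = np.array([l == cell_type for l in labels])
    values = data.values.astype(np.int64)
    gains = _gains_all_genes(values, in_type)

    n_in = int(in_type.sum())
    n11 = in_type.astype(np.int64) @ values
    n01 = values.sum(axis=0, dtype=np.int64) - n11
    order = sorted(range(len(symbols)), key=lambda i: (-gains[i], symbols[i]))[:n]
    table = pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "gene": [symbols[i] for i in order],
            "gain_bits": [float(gains[i]) for i in order],
            "n11": [int(n11[i]) for i in order],
            "n10": [n_in - int(n11[i]) for i in order],
            "n01": [int(n01[i]) for i in order],
            "n00": [(len(labels) - n_in) - int(n01[i]) for i in order],
        }
    )
    return SignatureRanking(cell_type=cell_type, table=table)
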