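"""Reading, writing and aligning expression matrices, labels and models.

Expression matrices are held genes-as-rows, cells-as-columns (the CellRanger
convention) in a :class:`ExpressionMatrix`.  Two on-disk dialects are
supported: the Matrix Market triplet layout (``matrix.mtx`` plus
``genes.tsv``/``features.tsv`` and ``barcodes.tsv``) and a dense delimited
table with gene rows and a header line of cell IDs.

A :class:`GeneSpace` fixes the identity and order of the classifier's input
nodes; ``align_to_gene_space`` projects an arbitrary dataset onto it,
dropping extraneous genes and zero-filling missing ones.  Trained models are
stored as a single zip archive holding a JSON manifest plus ``.npy`` weight
arrays and, optionally, a retained replay pool.
"""

from __future__ import annotations

import gzip
import json
import warnings
import zipfile
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse


class DataError(ValueError):
    """Malformed or inconsistent input data."""


MODEL_FORMAT_VERSION = 1


def _normalize_symbol(symbol: str) -> str:
    return symbol.strip().upper()


@dataclass
class GeneSpace:
    """Ordered reference gene list defining the model's input nodes."""

    symbols: list[str]

    def __post_init__(self) -> None:
        self.symbols = [_normalize_symbol(s) for s in self.symbols]
        if len(set(self.symbols)) != len(self.symbols):
            raise DataError("gene space contains duplicate symbols after normalization")
        if not self.symbols:
            raise DataError("gene space is empty")

    @property
    def size(self) -> int:
        return len(self.symbols)

    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.symbols)}

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256("\n".join(self.symbols).encode())
        return h.hexdigest()[:16]

    def __len__(self) -> int:
        return self.size

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GeneSpace) and self.symbols == other.symbols


@dataclass
class ExpressionMatrix:
    """UMI count matrix, genes x cells.

    ``counts`` is kept as a CSR sparse matrix; values are non-negative
    integers in UMI units.
    """

    genes: list[str]
    cells: list[str]
    counts: sparse.csr_matrix

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise DataError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.cells)) != len(self.cells):
            raise DataError("cell IDs are not unique")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise DataError("negative counts")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)


def _coerce_integral(data: np.ndarray, on_non_integer: str) -> np.ndarray:
    frac = data != np.floor(data)
    if np.any(frac):
        if on_non_integer == "error":
            raise DataError("matrix contains non-integer counts")
        warnings.warn(
            f"{int(frac.sum())} non-integer counts floored to integers",
            stacklevel=3,
        )
        data = np.floor(data)
    return data


def _open_maybe_gzip(path: Path):
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def _find_sidecar(directory: Path, stems: Sequence[str]) -> Path:
    for stem in stems:
        for suffix in ("", ".gz"):
            cand = directory / (stem + suffix)
            if cand.exists():
                return cand
    raise DataError(f"missing sidecar file: none of {list(stems)} in {directory}")


def read_expression_matrix(
    path: str | Path,
    format: str | None = None,
    *,
    on_non_integer: str = "floor",
) -> ExpressionMatrix:
    """Read a UMI count matrix from disk.

    Parameters
    ----------
    path
        For the MTX dialect, a directory containing ``matrix.mtx[.gz]``,
        a genes/features file and a barcodes file, or the path of the
        ``matrix.mtx`` itself.  For the dense dialect, a TSV/CSV file with
        gene rows and a header of cell IDs (first column = gene symbol).
    format
        ``"mtx-triplet"`` or ``"dense-delimited"``; inferred from the path
        when omitted.
    on_non_integer
        ``"floor"`` (warn and floor) or ``"error"``.
    """
    path = Path(path)
    if format is None:
        if path.is_dir() or path.name.startswith("matrix.mtx"):
            format = "mtx-triplet"
        else:
            format = "dense-delimited"
    if format == "mtx-triplet":
        return _read_mtx(path, on_non_integer)
    if format == "dense-delimited":
        return _read_dense(path, on_non_integer)
    raise ValueError(f"unknown format {format!r}")


def _read_mtx(path: Path, on_non_integer: str) -> ExpressionMatrix:
    directory = path if path.is_dir() else path.parent
    mtx_path = path if not path.is_dir() else _find_sidecar(directory, ["matrix.mtx"])
    genes_path = _find_sidecar(directory, ["genes.tsv", "features.tsv"])
    barcodes_path = _find_sidecar(directory, ["barcodes.tsv"])

    mat = spio.mmread(str(mtx_path))
    mat = sparse.coo_matrix(mat)
    genes_df = pd.read_csv(genes_path, sep="\t", header=None, dtype=str)
    # features file may be (ID,) or (ID, symbol[, type]); prefer the symbol column
    genes = list(genes_df.iloc[:, 1] if genes_df.shape[1] >= 2 else genes_df.iloc[:, 0])
    with _open_maybe_gzip(barcodes_path) as fh:
        cells = [line.strip().split("\t")[0] for line in fh if line.strip()]

    if mat.shape == (len(genes), len(cells)):
        pass
    elif mat.shape == (len(cells), len(genes)):
        mat = mat.T
    else:
        raise DataError(
            f"matrix dimensions {mat.shape} match neither "
            f"{len(genes)} genes x {len(cells)} cells nor its transpose"
        )
    data = _coerce_integral(np.asarray(mat.data, dtype=float), on_non_integer)
    counts = sparse.csr_matrix(
        (data.astype(np.int64), (mat.row, mat.col)), shape=mat.shape
    )
    return ExpressionMatrix(genes=genes, cells=cells, counts=counts)


def _read_dense(path: Path, on_non_integer: str) -> ExpressionMatrix:
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = _coerce_integral(df.to_numpy(dtype=float), on_non_integer)
    counts = sparse.csr_matrix(values.astype(np.int64))
    return ExpressionMatrix(
        genes=[str(g) for g in df.index],
        cells=[str(c) for c in df.columns],
        counts=counts,
    )


def write_expression_matrix(
    m: ExpressionMatrix, path: str | Path, format: str = "mtx-triplet"
) -> None:
    """Write a matrix in a dialect ``read_expression_matrix`` can read back."""
    path = Path(path)
    if format == "mtx-triplet":
        path.mkdir(parents=True, exist_ok=True)
        spio.mmwrite(str(path / "matrix.mtx"), sparse.coo_matrix(m.counts))
        with open(path / "genes.tsv", "w") as fh:
            for g in m.genes:
                fh.write(f"{g}\t{g}\n")
        with open(path / "barcodes.tsv", "w") as fh:
            fh.write("\n".join(m.cells) + ("\n" if m.cells else ""))
    elif format == "dense-delimited":
        df = pd.DataFrame(m.counts.toarray(), index=m.genes, columns=m.cells)
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_gene_space(path: str | Path) -> GeneSpace:
    """Read a one-column text file of gene symbols."""
    with _open_maybe_gzip(Path(path)) as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    return GeneSpace(symbols)


def write_gene_space(gs: GeneSpace, path: str | Path) -> None:
    Path(path).write_text("\n".join(gs.symbols) + "\n")


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV (cell_id, label) into a Series indexed by cell."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise DataError("label table must have two columns: cell_id, label")
    if df.iloc[0, 0] in ("cell_id", "cell", "barcode"):
        df = df.iloc[1:]
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].to_numpy(), name="label")
    if s.index.duplicated().any():
        raise DataError("duplicate cell IDs in label table")
    return s


def write_labels(labels: Mapping[str, str] | pd.Series, path: str | Path) -> None:
    s = pd.Series(labels)
    s.rename("label").rename_axis("cell_id").to_csv(path, sep="\t", header=False)


def align_to_gene_space(
    m: ExpressionMatrix,
    gs: GeneSpace,
    homolog_map: Mapping[str, str] | None = None,
    *,
    min_overlap_fraction: float = 0.2,
) -> ExpressionMatrix:
    """Project a matrix onto a reference gene space.

    Output gene order equals ``gs`` exactly: genes of ``m`` absent from
    ``gs`` are dropped and reference genes absent from ``m`` become all-zero
    rows.  Symbols are normalized (uppercased, stripped) and optionally
    translated through ``homolog_map`` before matching; duplicates collapsing
    onto one reference symbol are merged by element-wise maximum, which
    preserves presence under binarization.

    Raises
    ------
    DataError
        If fewer than ``min_overlap_fraction`` of the reference genes are
        found in ``m`` — the usual signature of a wrong species or wrong
        annotation build.
    """
    translate = {}
    if homolog_map:
        translate = {
            _normalize_symbol(k): _normalize_symbol(v) for k, v in homolog_map.items()
        }
    gs_index = gs.index()

    rows: dict[int, list[int]] = {}
    for i, raw in enumerate(m.genes):
        sym = _normalize_symbol(raw)
        sym = translate.get(sym, sym)
        j = gs_index.get(sym)
        if j is not None:
            rows.setdefault(j, []).append(i)

    overlap = len(rows) / gs.size
    if overlap < min_overlap_fraction:
        raise DataError(
            f"only {len(rows)}/{gs.size} reference genes found "
            f"({overlap:.1%} < {min_overlap_fraction:.0%}); wrong species or annotation?"
        )

    counts = sparse.lil_matrix((gs.size, m.n_cells), dtype=np.int64)
    src = sparse.csr_matrix(m.counts)
    for j, sources in rows.items():
        if len(sources) == 1:
            counts[j] = src[sources[0]]
        else:
            stacked = src[sources].toarray()
            counts[j] = stacked.max(axis=0)
    return ExpressionMatrix(
        genes=list(gs.symbols), cells=list(m.cells), counts=counts.tocsr()
    )


def read_homolog_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping source symbols to reference symbols."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


# ---------------------------------------------------------------------------
# Model archive


def save_model(model, path: str | Path, *, replay_pool=None) -> None:
    """Serialize a classifier to a single zip archive.

    The archive holds ``manifest.json`` (architecture, catalog, gene space,
    version tag, training metadata) and one ``.npy`` member per weight
    tensor.  When ``replay_pool`` — a ``(BinaryProfileMatrix, labels)``
    pair — is given it is stored alongside so later upgrades can replay
    previous training cells.
    """
    from .network import ClassifierModel  # deferred: avoid import cycle

    assert isinstance(model, ClassifierModel)
    manifest = {
        "format_version": MODEL_FORMAT_VERSION,
        "version": model.version,
        "config": {
            "input_size": model.config.input_size,
            "hidden_sizes": list(model.config.hidden_sizes),
            "dropout_rate": model.config.dropout_rate,
        },
        "catalog": {
            "known_types": model.catalog.known_types,
            "unknown_label": model.catalog.unknown_label,
        },
        "gene_space": model.gene_space.symbols,
        "gene_space_hash": model.gene_space.content_hash(),
        "n_layers": len(model.weights),
        "metadata": model.metadata,
        "has_replay_pool": replay_pool is not None,
    }
    path = Path(path)
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=1))
        for i, (W, b) in enumerate(model.weights):
            _write_npy(zf, f"W{i}.npy", W)
            _write_npy(zf, f"b{i}.npy", b)
        if replay_pool is not None:
            pool_matrix, pool_labels = replay_pool
            _write_npy(zf, "replay_values.npy", np.asarray(pool_matrix.values, dtype=np.uint8))
            zf.writestr("replay_cells.json", json.dumps(list(pool_matrix.cells)))
            zf.writestr("replay_labels.json", json.dumps(list(pool_labels)))


def _write_npy(zf: zipfile.ZipFile, name: str, arr: np.ndarray) -> None:
    import io as _io

    buf = _io.BytesIO()
    np.save(buf, np.ascontiguousarray(arr))
    zf.writestr(name, buf.getvalue())


def load_model(path: str | Path):
    """Load a model archive written by :func:`save_model`.

    Returns ``(model, replay_pool)`` where ``replay_pool`` is either
    ``None`` or a ``(BinaryProfileMatrix, labels)`` pair.
    """
    from .network import ClassifierModel, NetworkConfig
    from .preprocess import BinaryProfileMatrix, CellTypeCatalog

    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            manifest = json.loads(zf.read("manifest.json"))
            if manifest.get("format_version") != MODEL_FORMAT_VERSION:
                raise DataError(
                    f"unsupported model format version {manifest.get('format_version')!r}"
                )
            weights = []
            for i in range(manifest["n_layers"]):
                W = _read_npy(zf, f"W{i}.npy")
                b = _read_npy(zf, f"b{i}.npy")
                weights.append((W, b))
            replay = None
            if manifest.get("has_replay_pool"):
                values = _read_npy(zf, "replay_values.npy")
                cells = json.loads(zf.read("replay_cells.json"))
                labels = json.loads(zf.read("replay_labels.json"))
                gs = GeneSpace(manifest["gene_space"])
                replay = (
                    BinaryProfileMatrix(gene_space=gs, cells=cells, values=values),
                    labels,
                )
    except (zipfile.BadZipFile, KeyError, json.JSONDecodeError) as exc:
        raise DataError(f"corrupt or truncated model archive {path}: {exc}") from exc

    gene_space = GeneSpace(manifest["gene_space"])
    catalog = CellTypeCatalog(
        known_types=manifest["catalog"]["known_types"],
        unknown_label=manifest["catalog"]["unknown_label"],
    )
    cfg = NetworkConfig(
        input_size=manifest["config"]["input_size"],
        hidden_sizes=tuple(manifest["config"]["hidden_sizes"]),
        dropout_rate=manifest["config"]["dropout_rate"],
    )
    model = ClassifierModel(
        config=cfg,
        weights=weights,
        catalog=catalog,
        gene_space=gene_space,
        version=manifest["version"],
        metadata=manifest.get("metadata", {}),
    )
    return model, replay


def _read_npy(zf: zipfile.ZipFile, name: str) -> np.ndarray:
    import io as _io

    return np.load(_io.BytesIO(zf.read(name)), allow_pickle=False)
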