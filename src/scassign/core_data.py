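"""Data model and I/O shared by every pipeline stage.

The central container is :class:`AnnotatedMatrix`: a cells x features value
matrix (dense ndarray or scipy sparse) carrying per-cell and per-feature
metadata tables, named embeddings, and named layers (``"counts"`` holds raw
counts after normalization).  Matrices read from disk are stored sparse
whenever density < 50%; every operation in the package must behave
identically for sparse and dense backing.

Partitions (per-cell integer cluster labels plus an optional frozen mask)
and genomic intervals (0-based half-open) also live here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from .errors import FormatError, ParameterError

log = logging.getLogger(__name__)

SPARSE_DENSITY_THRESHOLD = 0.5


def _as_str_array(ids) -> np.ndarray:
    return np.asarray([str(x) for x in ids], dtype=object)


def maybe_sparsify(values):
    """Store sparse when density < 50%, dense otherwise."""
    if sp.issparse(values):
        density = values.nnz / max(1, values.shape[0] * values.shape[1])
        return values.tocsr() if density < SPARSE_DENSITY_THRESHOLD else np.asarray(values.todense())
    values = np.asarray(values, dtype=float)
    if values.size and np.count_nonzero(values) / values.size < SPARSE_DENSITY_THRESHOLD:
        return sp.csr_matrix(values)
    return values


def to_dense(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.todense())
    return np.asarray(values)


class AnnotatedMatrix:
    """Cells x features values plus metadata, embeddings and layers.

    Parameters
    ----------
    values : array or sparse matrix, cells x features
    cell_ids, feature_ids : unique string identifiers
    cell_meta, feature_meta : optional DataFrames aligned to the ids
    embeddings : name -> cells x d array
    layers : name -> same-shape matrix (``"counts"`` must be non-negative)
    """

    def __init__(self, values, cell_ids, feature_ids, cell_meta=None,
                 feature_meta=None, embeddings=None, layers=None):
        self.cell_ids = _as_str_array(cell_ids)
        self.feature_ids = _as_str_array(feature_ids)
        for name, ids in (("cell", self.cell_ids), ("feature", self.feature_ids)):
            if len(set(ids)) != len(ids):
                dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique()[:5]
                raise FormatError(f"duplicate {name} ids (e.g. {list(dupes)})")
        self.values = maybe_sparsify(values)
        if self.values.shape != (len(self.cell_ids), len(self.feature_ids)):
            raise FormatError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.feature_ids)} features")
        self.cell_meta = (pd.DataFrame(index=self.cell_ids) if cell_meta is None
                          else pd.DataFrame(cell_meta).set_axis(self.cell_ids, axis=0))
        self.feature_meta = (pd.DataFrame(index=self.feature_ids) if feature_meta is None
                             else pd.DataFrame(feature_meta).set_axis(self.feature_ids, axis=0))
        self.embeddings: dict[str, np.ndarray] = {}
        for name, emb in (embeddings or {}).items():
            self.set_embedding(name, emb)
        self.layers: dict = {}
        for name, layer in (layers or {}).items():
            self.set_layer(name, layer)

    # -- basic surface -------------------------------------------------
    @property
    def shape(self):
        return self.values.shape

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def dense_values(self) -> np.ndarray:
        return to_dense(self.values)

    def set_embedding(self, name: str, emb) -> None:
        emb = np.asarray(emb, dtype=float)
        if emb.shape[0] != self.n_cells:
            raise FormatError(f"embedding {name!r} has {emb.shape[0]} rows, expected {self.n_cells}")
        self.embeddings[name] = emb

    def set_layer(self, name: str, layer) -> None:
        layer = maybe_sparsify(layer)
        if layer.shape != self.shape:
            raise FormatError(f"layer {name!r} shape {layer.shape} != {self.shape}")
        if name == "counts":
            mn = layer.min() if not sp.issparse(layer) else (layer.data.min() if layer.nnz else 0.0)
            if mn < 0:
                raise FormatError("layer 'counts' contains negative values")
        self.layers[name] = layer

    def copy(self) -> "AnnotatedMatrix":
        out = AnnotatedMatrix(
            self.values.copy(), self.cell_ids.copy(), self.feature_ids.copy())
        out.cell_meta = self.cell_meta.copy()
        out.feature_meta = self.feature_meta.copy()
        out.embeddings = {k: v.copy() for k, v in self.embeddings.items()}
        out.layers = {k: v.copy() for k, v in self.layers.items()}
        return out

    def subset(self, cell_idx=None, feature_idx=None) -> "AnnotatedMatrix":
        """Positional subset preserving order; layers/meta/embeddings follow."""
        ci = np.arange(self.n_cells) if cell_idx is None else np.asarray(cell_idx)
        fi = np.arange(self.n_features) if feature_idx is None else np.asarray(feature_idx)
        vals = self.values[ci][:, fi] if sp.issparse(self.values) else self.values[np.ix_(ci, fi)]
        out = AnnotatedMatrix(vals, self.cell_ids[ci], self.feature_ids[fi])
        out.cell_meta = self.cell_meta.iloc[ci].copy()
        out.feature_meta = self.feature_meta.iloc[fi].copy()
        out.embeddings = {k: v[ci] for k, v in self.embeddings.items()}
        for name, layer in self.layers.items():
            out.layers[name] = (layer[ci][:, fi] if sp.issparse(layer)
                                else layer[np.ix_(ci, fi)])
        return out


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open [start, end) genomic span."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise FormatError(f"invalid interval {self.chrom}:{self.start}-{self.end}")
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"invalid strand {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (self.chrom == other.chrom
                and self.start < other.end and other.start < self.end)


@dataclass
class Partition:
    """Per-cell integer cluster labels plus an optional frozen mask."""

    labels: np.ndarray
    frozen: np.ndarray = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 1:
            raise ParameterError("labels must be 1-D")
        if (self.labels < 0).any():
            raise ParameterError("labels must be >= 0")
        if self.frozen is None:
            self.frozen = np.zeros(len(self.labels), dtype=bool)
        else:
            self.frozen = np.asarray(self.frozen, dtype=bool)
            if self.frozen.shape != self.labels.shape:
                raise ParameterError("frozen mask length mismatch")

    def __len__(self):
        return len(self.labels)

    @property
    def n_clusters(self) -> int:
        return len(np.unique(self.labels))


def canonicalize(partition: Partition):
    """Relabel to 0..K-1 by order of first appearance.

    Returns ``(canonical_partition, mapping)`` where ``mapping`` sends old
    labels to new ones.  Idempotent; the frozen mask is untouched.
    """
    mapping: dict[int, int] = {}
    new = np.empty(len(partition), dtype=int)
    for i, lab in enumerate(partition.labels):
        if lab not in mapping:
            mapping[int(lab)] = len(mapping)
        new[i] = mapping[int(lab)]
    return Partition(new, partition.frozen.copy()), mapping


@dataclass
class NeighborGraph:
    """Undirected unweighted kNN graph (union-symmetrized directed lists)."""

    n_cells: int
    edges: set  # of (i, j) tuples with i < j
    k: int

    def __post_init__(self):
        for i, j in self.edges:
            if i == j:
                raise ParameterError(f"self-loop at node {i}")
            if not (0 <= i < self.n_cells and 0 <= j < self.n_cells):
                raise ParameterError(f"edge ({i},{j}) out of range")
        self.edges = {(min(i, j), max(i, j)) for i, j in self.edges}

    def adjacency(self) -> list:
        adj = [[] for _ in range(self.n_cells)]
        for i, j in sorted(self.edges):
            adj[i].append(j)
            adj[j].append(i)
        return adj

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_cells, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg


# ---------------------------------------------------------------------------
# I/O


def read_mtx(matrix_path, barcodes_path, features_path,
             cells_in_rows: bool | None = None) -> AnnotatedMatrix:
    """Read a MatrixMarket matrix with barcode/feature TSV sidecars.

    Orientation on disk is inferred from the sidecar lengths: whichever
    axis matches the barcode count becomes the cell axis.  A square matrix
    with equal sidecar lengths is ambiguous and requires ``cells_in_rows``.
    Raw values are kept in layer ``"counts"``.
    """
    mat = mmread(str(matrix_path))
    barcodes = _read_id_column(barcodes_path)
    features = _read_id_column(features_path)
    nb, nf = len(barcodes), len(features)
    r, c = mat.shape
    if cells_in_rows is None:
        if (r, c) == (nb, nf) and (r, c) == (nf, nb):
            raise FormatError(
                f"{matrix_path}: square matrix with equal sidecar lengths is "
                "ambiguous; pass cells_in_rows explicitly")
        if (r, c) == (nb, nf):
            cells_in_rows = True
        elif (r, c) == (nf, nb):
            cells_in_rows = False
        else:
            raise FormatError(
                f"{matrix_path}: shape {mat.shape} matches neither "
                f"{nb} barcodes x {nf} features nor its transpose")
    if not cells_in_rows:
        mat = mat.T
        if mat.shape != (nb, nf):
            raise FormatError(
                f"{matrix_path}: shape {mat.T.shape} with cells_in_rows=False "
                f"does not match {nb} barcodes x {nf} features")
    elif mat.shape != (nb, nf):
        raise FormatError(
            f"{matrix_path}: shape {mat.shape} with cells_in_rows=True "
            f"does not match {nb} barcodes x {nf} features")
    m = AnnotatedMatrix(mat, barcodes, features)
    m.set_layer("counts", m.values.copy())
    return m


def _read_id_column(path) -> list:
    ids = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line:
                ids.append(line.split("\t")[0])
    return ids


def read_csv_matrix(path, cells_in_rows: bool = True) -> AnnotatedMatrix:
    """Read a dense CSV with a header row and a leading id column."""
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed CSV ({exc})") from exc
    body = df.to_numpy()
    if body.dtype == object or not np.issubdtype(body.dtype, np.number):
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            if coerced.isna().any() and not df[col].isna().any():
                row = int(np.where(coerced.isna())[0][0])
                raise FormatError(
                    f"{path}: non-numeric value at row {df.index[row]!r}, "
                    f"column {col!r}")
        body = df.apply(pd.to_numeric).to_numpy()
    if not cells_in_rows:
        df = df.T
        body = body.T
    m = AnnotatedMatrix(body, list(df.index), list(df.columns))
    return m


def write_labels_tsv(matrix: AnnotatedMatrix, label_key: str, path) -> None:
    """Write a two-column (cell_id, label) TSV in input cell order."""
    if label_key not in matrix.cell_meta.columns:
        raise KeyError(
            f"label key {label_key!r} not in cell_meta; available: "
            f"{list(matrix.cell_meta.columns)}")
    out = pd.DataFrame({"cell_id": matrix.cell_ids,
                        label_key: matrix.cell_meta[label_key].to_numpy()})
    out.to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"cell_id": str})


def write_mtx(matrix: AnnotatedMatrix, matrix_path, barcodes_path, features_path) -> None:
    """Write cells x features MTX plus sidecars (cells in rows)."""
    from scipy.io import mmwrite
    mmwrite(str(matrix_path), sp.coo_matrix(matrix.values))
    for path, ids in ((barcodes_path, matrix.cell_ids), (features_path, matrix.feature_ids)):
        with open(path, "w", encoding="utf-8") as fh:
            for x in ids:
                fh.write(f"{x}\n")


def write_embedding_csv(matrix: AnnotatedMatrix, name: str, path) -> None:
    emb = matrix.embeddings[name]
    cols = {f"dim{i}": emb[:, i] for i in range(emb.shape[1])}
    pd.DataFrame({"cell_id": matrix.cell_ids, **cols}).to_csv(path, index=False)
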