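"""QC filtering, library-size normalization and per-gene scaling.

The pipeline order is fixed: filter cells by expressed-gene count, filter
genes by expressing-cell count (each applied once, in that order), scale
each cell to a fixed total (CPM-style, default 1e5), log1p, then center and
scale every gene to unit variance.  Boundary values of the QC bounds are
kept ("expressed" means strictly positive).  Spatial proteomics panels
(CODEX) bypass filtering and normalization entirely: the measured channel
intensities pass through unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .core_data import AnnotatedMatrix, maybe_sparsify, to_dense
from .errors import EmptyResultError, ParameterError

log = logging.getLogger(__name__)


@dataclass
class QCParams:
    min_genes_per_cell: int = 50
    max_genes_per_cell: int = 3000
    min_cells_per_gene: int = 50
    max_cells_per_gene: int = 3000
    target_sum: float = 1e5

    def __post_init__(self):
        if not (0 <= self.min_genes_per_cell <= self.max_genes_per_cell):
            raise ParameterError("need 0 <= min_genes_per_cell <= max_genes_per_cell")
        if not (0 <= self.min_cells_per_gene <= self.max_cells_per_gene):
            raise ParameterError("need 0 <= min_cells_per_gene <= max_cells_per_gene")
        if self.target_sum <= 0:
            raise ParameterError("target_sum must be > 0")


def _counts(m: AnnotatedMatrix):
    if "counts" not in m.layers:
        raise ParameterError("layer 'counts' required")
    return m.layers["counts"]


def _nnz_per_row(mat) -> np.ndarray:
    if sp.issparse(mat):
        return np.asarray((mat > 0).sum(axis=1)).ravel()
    return (np.asarray(mat) > 0).sum(axis=1)


def _nnz_per_col(mat) -> np.ndarray:
    if sp.issparse(mat):
        return np.asarray((mat > 0).sum(axis=0)).ravel()
    return (np.asarray(mat) > 0).sum(axis=0)


def filter_cells(m: AnnotatedMatrix, p: QCParams) -> AnnotatedMatrix:
    """Keep cells expressing between min and max genes, inclusive."""
    n_expressed = _nnz_per_row(_counts(m))
    keep = (n_expressed >= p.min_genes_per_cell) & (n_expressed <= p.max_genes_per_cell)
    if not keep.any():
        raise EmptyResultError(
            f"cell filter [{p.min_genes_per_cell}, {p.max_genes_per_cell}] "
            f"removed all {m.n_cells} cells")
    log.info("filter_cells: removed %d of %d cells", int((~keep).sum()), m.n_cells)
    return m.subset(cell_idx=np.where(keep)[0])


def filter_genes(m: AnnotatedMatrix, p: QCParams) -> AnnotatedMatrix:
    """Keep genes expressed in between min and max cells, inclusive."""
    n_cells_expr = _nnz_per_col(_counts(m))
    keep = (n_cells_expr >= p.min_cells_per_gene) & (n_cells_expr <= p.max_cells_per_gene)
    if not keep.any():
        raise EmptyResultError(
            f"gene filter [{p.min_cells_per_gene}, {p.max_cells_per_gene}] "
            f"removed all {m.n_features} genes")
    log.info("filter_genes: removed %d of %d genes", int((~keep).sum()), m.n_features)
    return m.subset(feature_idx=np.where(keep)[0])


def normalize_cpm_log1p(m: AnnotatedMatrix, target_sum: float = 1e5) -> AnnotatedMatrix:
    """Scale each cell to ``target_sum`` total counts, then log1p.

    Raw counts are kept in layer ``"counts"``; values become the normalized
    log expression on which PCA, DE and label transfer operate.
    """
    counts = _counts(m)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    if (totals <= 0).any():
        bad = m.cell_ids[np.where(totals <= 0)[0][0]]
        raise EmptyResultError(f"cell {bad!r} has zero total count; cannot normalize")
    out = m.copy()
    if sp.issparse(counts):
        scaled = sp.diags(target_sum / totals) @ counts.tocsr()
        scaled.data = np.log1p(scaled.data)
        out.values = scaled
    else:
        out.values = np.log1p(np.asarray(counts) * (target_sum / totals)[:, None])
    out.layers["counts"] = counts.copy()
    return out


def scale_unit_variance(m: AnnotatedMatrix) -> AnnotatedMatrix:
    """Center each gene and scale to unit population (ddof=0) variance.

    Zero-variance genes are centered only.  No clipping is applied.
    Output is always dense (centering destroys sparsity).
    """
    x = to_dense(m.values).astype(float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    out = m.copy()
    out.values = (x - mean) / sd_safe
    return out


def preprocess_pipeline(m: AnnotatedMatrix, p: QCParams | None = None,
                        skip_normalization: bool = False) -> AnnotatedMatrix:
    """filter cells -> filter genes -> CPM/log1p -> unit-variance scaling.

    With ``skip_normalization=True`` (the CODEX path) the input passes
    through bit-identical: no filtering, no normalization, no scaling.
    """
    if skip_normalization:
        return m.copy()
    p = p or QCParams()
    m = filter_cells(m, p)
    m = filter_genes(m, p)
    m = normalize_cpm_log1p(m, p.target_sum)
    lognorm = m.values.copy()
    m = scale_unit_variance(m)
    m.layers["lognorm"] = lognorm  # kept for DE/fold-change, which need pre-scaling values
    return m
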