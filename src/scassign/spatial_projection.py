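"""Cluster assignments projected onto per-cell spatial centroids.

For imaging assays (CODEX-style multiplexed proteomics) each cell carries
a centroid in pixel coordinates (origin top-left, y increasing downward).
The side-by-side view draws the 2-D expression embedding and the spatial
scatter with one shared, deterministic palette, so a cluster has the same
color in both panels.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")  # headless rendering only
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .core_data import Partition
from .errors import FormatError, ParameterError


@dataclass
class SpatialMap:
    cell_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.cell_ids = np.asarray([str(c) for c in self.cell_ids], dtype=object)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.cell_ids) == len(self.x) == len(self.y)):
            raise FormatError("cell_ids, x, y must have equal length")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise FormatError("non-finite spatial coordinates")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell_id in spatial map")

    def __len__(self):
        return len(self.cell_ids)


def read_spatial_csv(path) -> SpatialMap:
    """CSV with cell_id, x, y columns (extra columns ignored)."""
    df = pd.read_csv(path)
    for col in ("cell_id", "x", "y"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    for col in ("x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            row = int(np.where(coerced.isna())[0][0])
            raise FormatError(f"{path}: non-numeric {col!r} at data row {row}")
        df[col] = coerced
    return SpatialMap(df["cell_id"].astype(str).to_numpy(),
                      df["x"].to_numpy(), df["y"].to_numpy())


def cluster_palette(partition: Partition) -> dict[int, tuple]:
    """Deterministic, pairwise-distinct RGBA color per cluster id.

    The first 20 clusters use the tab20 qualitative palette; beyond that,
    evenly spaced HSV hues keep colors distinct for any K.
    """
    ids = sorted(int(c) for c in np.unique(partition.labels))
    k = len(ids)
    if k == 0:
        raise ParameterError("empty partition")
    tab20 = plt.get_cmap("tab20")
    hsv = plt.get_cmap("hsv")
    palette = {}
    for rank, c in enumerate(ids):
        if rank < 20 and k <= 20:
            palette[c] = tuple(tab20(rank % 20))
        else:
            palette[c] = tuple(hsv(rank / k))
    return palette


def palette_table(palette: dict[int, tuple], path=None):
    rows = [{"cluster": c,
             "color": matplotlib.colors.to_hex(rgba)}
            for c, rgba in sorted(palette.items())]
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df


def render_side_by_side(embedding_2d, spatial: SpatialMap, partition: Partition,
                        out_path, cell_ids=None, point_size: float = 8.0) -> dict:
    """Two-panel PNG: 2-D embedding and spatial scatter, shared palette.

    All three inputs are aligned by cell order; if ``cell_ids`` is given
    the spatial map is matched by id instead and missing ids are an error.
    Returns the palette used (cluster id -> RGBA).
    """
    emb = np.asarray(embedding_2d, dtype=float)
    if len(partition) == 0:
        raise ParameterError("empty partition")
    if emb.shape[0] != len(partition):
        raise ParameterError("embedding and partition length differ")
    if cell_ids is not None:
        pos = {c: i for i, c in enumerate(spatial.cell_ids)}
        missing = [c for c in cell_ids if str(c) not in pos]
        if missing:
            raise ParameterError(
                f"spatial map lacks {len(missing)} cell ids (first 5): {missing[:5]}")
        order = [pos[str(c)] for c in cell_ids]
        sx, sy = spatial.x[order], spatial.y[order]
    else:
        if len(spatial) != len(partition):
            raise ParameterError("spatial map and partition length differ")
        sx, sy = spatial.x, spatial.y

    palette = cluster_palette(partition)
    colors = np.array([palette[int(c)] for c in partition.labels])
    fig, (ax_a, ax_b) = plt.subplots(1, 2, figsize=(11, 5))
    ax_a.scatter(emb[:, 0], emb[:, 1], c=colors, s=point_size, linewidths=0)
    ax_a.set_title("expression embedding")
    ax_b.scatter(sx, sy, c=colors, s=point_size, linewidths=0)
    ax_b.invert_yaxis()  # image convention: origin top-left, y downward
    ax_b.set_aspect("equal")
    ax_b.set_title("spatial centroids")
    handles = [plt.Line2D([], [], marker="o", linestyle="", color=palette[c],
                          label=str(c)) for c in sorted(palette)]
    ax_b.legend(handles=handles, title="cluster", loc="center left",
                bbox_to_anchor=(1.02, 0.5), fontsize=7)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120, metadata={"Software": None})
    plt.close(fig)
    return palette
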