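"""Synthetic data generators: a download-free test surface for every stage.

The count model is clustered negative-binomial with dropout: each cluster
up-regulates its own block of marker genes by a planted log2 fold change
on top of shared lognormal base means.  Companion generators produce a
peak/GTF fixture for gene-activity scoring (with an exhaustive brute-force
oracle), a reference/query pair for label transfer with cluster-structured
reference-label noise, and spatially coherent blob centroids.

All generators are pure functions of their spec (seed included).  This
module also hosts the exact oracles used against the clustering engine:
exhaustive enumeration of (constraint-satisfying) partitions on tiny
graphs, and a family of small graphs exercising frozen-mask corner cases.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core_data import AnnotatedMatrix, GenomicInterval, NeighborGraph, Partition
from .errors import ParameterError
from .preprocess import QCParams
from .embed_cluster import partition_quality
from .spatial_projection import SpatialMap


@dataclass
class FixtureSpec:
    n_cells: int = 480
    n_genes: int = 800
    n_clusters: int = 6
    de_fraction: float = 0.2    # fraction of genes up-regulated per cluster
    de_log2fc: float = 3.0      # planted effect size
    nb_dispersion: float = 0.5  # NB overdispersion (var = mu + disp * mu^2)
    dropout_rate: float = 0.3
    seed: int = 0
    spatial_layout: str = "none"  # blobs | none
    transfer_noise: float = 0.0   # fraction of reference labels corrupted

    def __post_init__(self):
        for name in ("de_fraction", "dropout_rate", "transfer_noise"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ParameterError(f"{name}={v} must be in [0, 1]")
        if self.n_cells <= 0 or self.n_genes <= 0 or self.n_clusters <= 0:
            raise ParameterError("counts must be positive")
        if self.n_clusters > self.n_cells:
            raise ParameterError("n_clusters > n_cells")
        if self.spatial_layout not in ("blobs", "none"):
            raise ParameterError(f"unknown spatial_layout {self.spatial_layout!r}")


def fixture_qc_params(spec: FixtureSpec) -> QCParams:
    """QC bounds rescaled to fixture size (the defaults assume full-size data)."""
    return QCParams(min_genes_per_cell=5, max_genes_per_cell=spec.n_genes,
                    min_cells_per_gene=3, max_cells_per_gene=spec.n_cells)


def _nb_draw(rng, mu, dispersion):
    # var = mu + dispersion * mu^2  (r = 1/dispersion)
    r = 1.0 / max(dispersion, 1e-9)
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def _cluster_means(spec: FixtureSpec, rng):
    base = rng.lognormal(mean=0.7, sigma=0.6, size=spec.n_genes)
    n_marker = max(1, int(round(spec.de_fraction * spec.n_genes)))
    order = rng.permutation(spec.n_genes)
    marker_of = np.full(spec.n_genes, -1)
    mu = np.tile(base, (spec.n_clusters, 1))
    for c in range(spec.n_clusters):
        block = order[c * n_marker:(c + 1) * n_marker]
        marker_of[block] = c
        mu[c, block] *= 2.0 ** spec.de_log2fc
    return mu, marker_of


def _draw_counts(spec: FixtureSpec, rng, cell_mu):
    counts = _nb_draw(rng, cell_mu, spec.nb_dispersion).astype(float)
    if spec.dropout_rate > 0:
        counts *= rng.random(counts.shape) >= spec.dropout_rate
    return counts


def make_counts(spec: FixtureSpec, cell_prefix: str = "cell"):
    """Clustered NB counts with planted markers; returns (matrix, truth)."""
    rng = np.random.default_rng(spec.seed)
    mu, marker_of = _cluster_means(spec, rng)
    labels = rng.integers(0, spec.n_clusters, spec.n_cells)
    counts = _draw_counts(spec, rng, mu[labels])
    m = AnnotatedMatrix(counts,
                        [f"{cell_prefix}{i}" for i in range(spec.n_cells)],
                        [f"gene{j}" for j in range(spec.n_genes)])
    m.set_layer("counts", m.values.copy())
    m.cell_meta["truth"] = labels
    m.feature_meta["marker_cluster"] = marker_of
    return m, Partition(labels)


# ---------------------------------------------------------------------------
# scATAC fixture


def make_atac_fixture(spec: FixtureSpec, out_dir):
    """Toy peak matrix + GTF + exhaustive activity oracle.

    ~50 peaks over three toy chromosomes and ~20 genes on both strands,
    deliberately including a near-origin gene (extension clipping) and
    peaks placed exactly at extended-range edges (half-open boundary).
    The oracle is the O(peaks x genes) double loop over overlap tests with
    the default extension parameters.

    Returns ``(peaks_by_cells, gtf_path, oracle, gene_ids)`` with the
    oracle a dense cells x genes array in GTF gene order.
    """
    from .atac_gene_activity import ExtensionParams, GeneRange, extend_range

    rng = np.random.default_rng(spec.seed)
    chroms = ["chrA", "chrB", "chrC"]
    genes = []
    for gi in range(20):
        chrom = chroms[gi % 3]
        if gi == 0:
            start = int(rng.integers(0, 800))  # clipping case: upstream hits 0
        else:
            start = int(rng.integers(1000, 80000))
        length = int(rng.integers(500, 3000))
        strand = "+" if gi % 2 == 0 else "-"
        genes.append(GeneRange(f"g{gi}", f"G{gi}",
                               GenomicInterval(chrom, start, start + length, strand)))
    p = ExtensionParams()
    peaks = []
    for pi in range(44):
        chrom = chroms[int(rng.integers(0, 3))]
        start = int(rng.integers(0, 95000))
        peaks.append(GenomicInterval(chrom, start, start + int(rng.integers(150, 600)), "."))
    # boundary peaks around the first three genes' extended ranges
    for gene in genes[:3]:
        ext = extend_range(gene, p)
        peaks.append(GenomicInterval(ext.chrom, ext.end, ext.end + 200, "."))          # no overlap
        peaks.append(GenomicInterval(ext.chrom, max(0, ext.end - 1), ext.end + 199, "."))  # 1 bp overlap
    peak_ids = [f"{pk.chrom}:{pk.start}-{pk.end}" for pk in peaks]

    n_cells = min(spec.n_cells, 40)
    counts = rng.poisson(1.2, size=(n_cells, len(peaks))).astype(float)
    m = AnnotatedMatrix(counts, [f"atac{i}" for i in range(n_cells)], peak_ids)
    m.set_layer("counts", m.values.copy())

    gtf_path = str(out_dir) + "/toy_genes.gtf"
    with open(gtf_path, "w", encoding="utf-8") as fh:
        for g in genes:
            iv = g.interval
            fh.write(f"{iv.chrom}\ttoy\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                     f"{iv.strand}\t.\tgene_id \"{g.gene_id}\"; "
                     f"gene_name \"{g.gene_name}\";\n")

    oracle = np.zeros((n_cells, len(genes)))
    for gi, g in enumerate(genes):
        ext = extend_range(g, p)
        for pi, pk in enumerate(peaks):
            if pk.overlaps(ext):
                oracle[:, gi] += counts[:, pi]
    return m, gtf_path, oracle, [g.gene_id for g in genes]


# ---------------------------------------------------------------------------
# label-transfer fixture


def make_transfer_pair(spec: FixtureSpec):
    """Reference/query pair emulating an annotated-atlas transfer experiment.

    Both datasets come from one cluster model; the query carries a mild
    per-gene multiplicative shift and the gene sets overlap by 80% (each
    side lacks a different 10%).  ``spec.n_clusters`` counts *annotation*
    (coarse) clusters; two features mirror how expert annotations behave
    in practice:

    * Coarse annotation over finer modular structure.  The first two
      coarse clusters ("clean" types) are each a union of three fully
      distinct fine cell types, annotated at the coarse level — a de-novo
      modularity clustering at default resolution finds (and is right to
      find) the fine types, but is scored against the expert's coarser
      truth.  The remaining clusters are unitary.
    * Cluster-structured annotation noise.  ``transfer_noise`` is the
      total fraction of reference cells whose label is corrupted.
      Corruption is confined to the unitary ("noisy") clusters, each
      corrupted cell relabeled to another noisy cluster — confusable
      types carry the annotation noise, the well-known types stay clean.
      Scattered wrong labels rarely flip a 15-neighbor vote but drag
      per-cell confidence down, so the noisy clusters fall below any
      sensible freezing bar while the clean types keep near-unanimous
      votes: the regime where freezing the least-noisy clusters and
      refining the rest pays off.

    Returns ``(reference, query, query_truth)``; the reference carries the
    noisy annotation in cell_meta["label"] and its truth in
    cell_meta["truth"].
    """
    if spec.n_clusters < 4:
        raise ParameterError("make_transfer_pair needs >= 4 coarse clusters")
    rng = np.random.default_rng(spec.seed)
    k = spec.n_clusters
    n_clean = 2
    n_fine = 3 * n_clean + (k - n_clean)
    # one disjoint marker block per fine type
    block = max(1, min(int(round(spec.de_fraction * spec.n_genes)),
                       spec.n_genes // n_fine))
    base = rng.lognormal(mean=0.7, sigma=0.6, size=spec.n_genes)
    order = rng.permutation(spec.n_genes)
    fc = 2.0 ** spec.de_log2fc
    mu = np.tile(base, (n_fine, 1))
    for f in range(n_fine):
        mu[f, order[f * block:(f + 1) * block]] *= fc

    def fine_of(coarse, rng):
        sub = rng.integers(0, 3, len(coarse))
        return np.where(coarse < n_clean, 3 * coarse + sub,
                        3 * n_clean + (coarse - n_clean))

    ref_labels = rng.integers(0, k, spec.n_cells)
    ref_counts = _draw_counts(spec, rng, mu[fine_of(ref_labels, rng)])
    qry_labels = rng.integers(0, k, spec.n_cells)
    shift = rng.lognormal(mean=0.0, sigma=0.15, size=spec.n_genes)
    qry_counts = _draw_counts(spec, rng, mu[fine_of(qry_labels, rng)] * shift)

    noisy_labels = ref_labels.copy()
    if spec.transfer_noise > 0:
        noisy_set = np.arange(n_clean, k)
        pool = np.where(np.isin(ref_labels, noisy_set))[0]
        n_target = min(len(pool), int(round(spec.transfer_noise * spec.n_cells)))
        corrupt = rng.choice(pool, size=n_target, replace=False)
        for i in corrupt:
            others = noisy_set[noisy_set != ref_labels[i]]
            noisy_labels[i] = int(others[int(rng.integers(len(others)))])

    n_drop = int(round(0.1 * spec.n_genes))
    gene_ids = np.array([f"gene{j}" for j in range(spec.n_genes)], dtype=object)
    ref_cols = np.arange(spec.n_genes) < spec.n_genes - n_drop  # drop last 10%
    qry_cols = np.arange(spec.n_genes) >= n_drop                # drop first 10%

    reference = AnnotatedMatrix(ref_counts[:, ref_cols],
                                [f"ref{i}" for i in range(spec.n_cells)],
                                gene_ids[ref_cols])
    reference.set_layer("counts", reference.values.copy())
    reference.cell_meta["label"] = noisy_labels
    reference.cell_meta["truth"] = ref_labels

    query = AnnotatedMatrix(qry_counts[:, qry_cols],
                            [f"qry{i}" for i in range(spec.n_cells)],
                            gene_ids[qry_cols])
    query.set_layer("counts", query.values.copy())
    query.cell_meta["truth"] = qry_labels
    return reference, query, qry_labels


# ---------------------------------------------------------------------------
# spatial fixture


def make_spatial_fixture(spec: FixtureSpec, truth: Partition,
                         cell_ids=None) -> SpatialMap:
    """Per-cluster Gaussian blobs on a 1000 x 1000 px tile.

    Blob centers sit on a circle of radius 350 around the tile center, so
    centers are >= 300 px apart for up to 7 clusters.
    """
    if spec.spatial_layout != "blobs":
        raise ParameterError("make_spatial_fixture requires spatial_layout='blobs'")
    rng = np.random.default_rng(spec.seed + 1)
    k = truth.n_clusters
    angles = 2 * np.pi * np.arange(k) / k
    centers = np.stack([500 + 350 * np.cos(angles), 500 + 350 * np.sin(angles)], axis=1)
    xy = centers[truth.labels] + rng.normal(0, 40, size=(len(truth), 2))
    xy = np.clip(xy, 0, 1000)
    ids = cell_ids if cell_ids is not None else [f"cell{i}" for i in range(len(truth))]
    return SpatialMap(np.asarray(ids, dtype=object), xy[:, 0], xy[:, 1])


# ---------------------------------------------------------------------------
# exact clustering oracles


def enumerate_labelings(n: int):
    """All set partitions of n items as restricted-growth label tuples."""
    def rec(prefix, mx):
        if len(prefix) == n:
            yield tuple(prefix)
            return
        for v in range(mx + 2):
            yield from rec(prefix + [v], max(mx, v))
    if n:
        yield from rec([0], 0)


def constraints_satisfied(labels, init, frozen) -> bool:
    """Frozen pairs: same init label <=> same final label."""
    fidx = np.where(np.asarray(frozen, dtype=bool))[0]
    init = np.asarray(init)
    labels = np.asarray(labels)
    for i, j in itertools.combinations(fidx, 2):
        if (init[i] == init[j]) != (labels[i] == labels[j]):
            return False
    return True


def bruteforce_best_partition(graph: NeighborGraph, resolution: float = 1.0,
                              init=None, frozen=None):
    """Exhaustive maximizer of the RB-configuration quality (tiny graphs).

    With ``init``/``frozen``, only constraint-satisfying partitions are
    considered.  Returns ``(labels, quality)``.
    """
    if graph.n_cells > 10:
        raise ParameterError("brute force is for graphs of <= 10 nodes")
    best, best_q = None, -np.inf
    for lab in enumerate_labelings(graph.n_cells):
        if frozen is not None and not constraints_satisfied(lab, init, frozen):
            continue
        q = partition_quality(graph, lab, resolution)
        if q > best_q:
            best, best_q = np.array(lab), q
    return best, best_q


def small_graph_family():
    """Graphs of <= 8 nodes with frozen masks, for exact-oracle checks.

    Structured cases (disjoint triangles, K5, barbell, path, cycle, star)
    plus seeded Erdos-Renyi draws, each paired with one or two
    (init, frozen, resolution) configurations.
    """
    cases = []

    def add(n, edges, init, frozen, res):
        cases.append((NeighborGraph(n, set(edges), 2),
                      np.asarray(init), np.asarray(frozen, dtype=bool), res))

    tri2 = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]
    add(6, tri2, [0] * 6, [False] * 6, 1.0)
    add(6, tri2, [0, 0, 0, 1, 1, 1], [True, True, True, False, False, False], 1.0)
    # one triangle frozen with a deliberately misplaced unfrozen member
    add(7, tri2 + [(2, 3), (5, 6), (4, 6), (3, 6)],
        [0, 0, 0, 1, 1, 1, 1], [True, True, True, False, False, False, False], 1.0)
    k5 = list(itertools.combinations(range(5), 2))
    add(5, k5, [0] * 5, [False] * 5, 1.0)
    add(5, k5, [0, 0, 1, 1, 2], [True, False, True, False, False], 1.0)
    barbell = [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5), (2, 3)]
    add(6, barbell, [0, 0, 0, 1, 1, 1], [True] * 6, 1.0)
    add(6, barbell, [0] * 6, [False] * 6, 1.0)
    path = [(i, i + 1) for i in range(7)]
    add(8, path, [0, 0, 0, 0, 1, 1, 1, 1], [True, False, False, False, False, False, False, True], 1.0)
    cycle = path + [(0, 7)]
    add(8, cycle, [0] * 8, [False] * 8, 0.5)
    star = [(0, i) for i in range(1, 8)]
    add(8, star, [0, 1, 1, 1, 2, 2, 2, 0], [False, True, False, False, True, False, False, False], 1.0)
    rng = np.random.default_rng(2024)
    for _ in range(24):
        n = int(rng.integers(5, 9))
        dens = float(rng.choice([0.35, 0.5, 0.65]))
        edges = {(i, j) for i, j in itertools.combinations(range(n), 2)
                 if rng.random() < dens}
        if not edges:
            continue
        init = rng.integers(0, 3, n)
        frozen = rng.random(n) < 0.4
        add(n, edges, init, frozen, float(rng.choice([0.5, 1.0, 1.5])))
    return cases
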