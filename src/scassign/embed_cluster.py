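"""Dimensionality reduction, kNN graphs, and (constrained) Leiden clustering.

The clustering engine is an in-package Leiden optimiser over the
RB-configuration modularity

    H(P) = sum_c [ w_in(c) - gamma * K_c^2 / (4m) ]

with resolution ``gamma``, intra-community edge weight ``w_in``, community
degree sum ``K_c`` and total edge weight ``m``.  It runs the three Leiden
phases (queue-based local moving, refinement within communities,
aggregation) and supports *frozen* nodes: cells whose community membership
is fixed for the whole run.  Frozen cells sharing an initial label always
end in the same community, frozen cells with different initial labels never
merge, and unfrozen cells may move freely — including into frozen
communities.  Every stochastic choice is driven by an explicit seed; the
optimiser restarts from several seeded node orders and keeps the best
quality, so results are deterministic given the seed.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score

from .core_data import AnnotatedMatrix, NeighborGraph, Partition, canonicalize, to_dense
from .errors import ParameterError

_EPS = 1e-12


@dataclass
class ReductionParams:
    n_components: int = 40
    method: str = "pca"  # pca | umap | precomputed
    umap_dims: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("pca", "umap", "precomputed"):
            raise ParameterError(f"unknown reduction method {self.method!r}")
        if self.n_components < 1:
            raise ParameterError("n_components must be >= 1")


@dataclass
class ClusterParams:
    k_neighbors: int = 15
    resolution: float = 1.0
    seed: int = 0
    max_iterations: int = 20
    n_restarts: int = 8

    def __post_init__(self):
        if self.k_neighbors < 1:
            raise ParameterError("k_neighbors must be >= 1")
        if self.resolution <= 0:
            raise ParameterError("resolution must be > 0")


# ---------------------------------------------------------------------------
# reductions


def reduce_pca(m: AnnotatedMatrix, p: ReductionParams, key: str = "reduced") -> AnnotatedMatrix:
    """PCA with a randomized SVD solver; embedding stored under ``key``."""
    max_comp = min(m.n_cells - 1, m.n_features)
    if p.n_components > max_comp:
        raise ParameterError(
            f"n_components={p.n_components} too large; admissible maximum is {max_comp}")
    x = to_dense(m.values)
    pca = PCA(n_components=p.n_components, svd_solver="randomized",
              random_state=p.seed)
    emb = pca.fit_transform(x)
    out = m.copy()
    out.set_embedding(key, emb)
    return out


def reduce_umap(m: AnnotatedMatrix, p: ReductionParams, source: str | None = None,
                key: str = "umap", n_dims: int | None = None,
                n_neighbors: int = 15) -> AnnotatedMatrix:
    """UMAP to ``n_dims`` dimensions (2 for visualization, 10 for the
    spatial-proteomics clustering path), deterministic given the seed."""
    import umap  # deferred: numba compilation is expensive at import

    n_dims = n_dims if n_dims is not None else p.umap_dims
    x = m.embeddings[source] if source else to_dense(m.values)
    if m.n_cells <= n_neighbors:
        raise ParameterError(
            f"n_neighbors={n_neighbors} requires more than {m.n_cells} cells")
    reducer = umap.UMAP(n_components=n_dims, n_neighbors=n_neighbors,
                        random_state=p.seed)
    emb = reducer.fit_transform(x)
    out = m.copy()
    out.set_embedding(key, np.asarray(emb, dtype=float))
    return out


# ---------------------------------------------------------------------------
# kNN graph


def build_knn_graph(embedding, k: int) -> NeighborGraph:
    """Exact Euclidean kNN, self excluded, union-symmetrized, unweighted.

    Ties at equal distance are broken toward the lower cell index (stable
    sort on the distance row).
    """
    x = np.asarray(embedding, dtype=float)
    n = x.shape[0]
    if k >= n:
        raise ParameterError(f"k={k} must be < n_cells={n}")
    sq = np.einsum("ij,ij->i", x, x)
    edges = set()
    # chunked exact search keeps memory bounded for larger fixtures
    chunk = max(1, int(2e7 // max(1, n)))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        d2 = sq[lo:hi, None] + sq[None, :] - 2.0 * (x[lo:hi] @ x.T)
        np.maximum(d2, 0.0, out=d2)
        for i in range(lo, hi):
            row = d2[i - lo]
            row[i] = np.inf
            nbrs = np.argsort(row, kind="stable")[:k]
            for j in nbrs:
                edges.add((min(i, int(j)), max(i, int(j))))
    return NeighborGraph(n_cells=n, edges=edges, k=k)


# ---------------------------------------------------------------------------
# Leiden optimiser internals


class _Graph:
    """Weighted graph with self-loop weights, for the aggregation levels."""

    __slots__ = ("n", "adj", "self_w", "strength", "total_w")

    def __init__(self, n, adj, self_w):
        self.n = n
        self.adj = adj            # list of dicts: neighbor -> weight
        self.self_w = self_w      # internal weight carried by the node
        self.strength = np.array(
            [sum(a.values()) + 2.0 * s for a, s in zip(adj, self_w)])
        self.total_w = sum(sum(a.values()) for a in adj) / 2.0 + sum(self_w)

    @classmethod
    def from_neighbor_graph(cls, g: NeighborGraph) -> "_Graph":
        adj = [dict() for _ in range(g.n_cells)]
        for i, j in g.edges:
            adj[i][j] = adj[i].get(j, 0.0) + 1.0
            adj[j][i] = adj[j].get(i, 0.0) + 1.0
        return cls(g.n_cells, adj, [0.0] * g.n_cells)


def _quality(g: _Graph, memb, gamma: float) -> float:
    w_in = defaultdict(float)
    K = defaultdict(float)
    for v in range(g.n):
        c = memb[v]
        K[c] += g.strength[v]
        w_in[c] += g.self_w[v]
        for u, w in g.adj[v].items():
            if u > v and memb[u] == c:
                w_in[c] += w
    m4 = 4.0 * g.total_w
    return float(sum(w_in[c] - gamma * K[c] ** 2 / m4 for c in K))


def partition_quality(graph: NeighborGraph, labels, resolution: float = 1.0) -> float:
    """RB-configuration quality of a labeling on a kNN graph (public, for
    comparing partitions and for exhaustive oracles in tests)."""
    g = _Graph.from_neighbor_graph(graph)
    return _quality(g, np.asarray(labels, dtype=int), resolution)


def _local_move(g: _Graph, memb, frozen, gamma: float, rng) -> bool:
    """Queue-based local moving; frozen nodes are never moved."""
    n = g.n
    K = defaultdict(float)
    for v in range(n):
        K[memb[v]] += g.strength[v]
    m2 = 2.0 * g.total_w
    order = rng.permutation(n)
    queue = deque(int(v) for v in order)
    in_queue = np.ones(n, dtype=bool)
    next_free = max(memb) + 1 if n else 0
    moved_any = False
    budget = 100 * n + 100  # zero-gain moves are allowed; cap guarantees termination
    while queue and budget > 0:
        budget -= 1
        v = queue.popleft()
        in_queue[v] = False
        if frozen[v]:
            continue
        cv = memb[v]
        kv = g.strength[v]
        wtc = defaultdict(float)
        for u, w in g.adj[v].items():
            wtc[memb[u]] += w
        stay = wtc.get(cv, 0.0) - gamma * kv * (K[cv] - kv) / m2
        # candidates: stay, every neighboring community, a fresh singleton
        cands = [(cv, 0.0), (next_free, -stay)]
        for d in sorted(wtc):
            if d != cv:
                cands.append((d, wtc[d] - gamma * kv * K[d] / m2 - stay))
        best_gain = max(gain for _, gain in cands)
        # random tie-break among maximal candidates: zero-gain moves let the
        # optimiser walk plateaus that strict improvement cannot cross
        ties = [c for c, gain in cands if gain >= best_gain - _EPS]
        best_c = ties[rng.integers(len(ties))] if len(ties) > 1 else ties[0]
        if best_c != cv:
            K[cv] -= kv
            K[best_c] += kv
            memb[v] = best_c
            if best_c == next_free:
                next_free += 1
            moved_any = True
            for u in g.adj[v]:
                if memb[u] != best_c and not in_queue[u] and not frozen[u]:
                    queue.append(u)
                    in_queue[u] = True
    return moved_any


def _refine(g: _Graph, memb, frozen, gamma: float, rng):
    """Split each community into well-merged subcommunities.

    Frozen nodes of a community form one atomic subcommunity (refinement
    never splits a frozen set); unfrozen singletons greedily merge into the
    best adjacent subcommunity within their community.
    """
    n = g.n
    sub = np.arange(n)
    frozen_anchor: dict[int, int] = {}
    for v in range(n):
        if frozen[v]:
            c = memb[v]
            if c in frozen_anchor:
                sub[v] = frozen_anchor[c]
            else:
                frozen_anchor[c] = v
    subK = defaultdict(float)
    sub_size = defaultdict(int)
    for v in range(n):
        subK[sub[v]] += g.strength[v]
        sub_size[sub[v]] += 1
    m2 = 2.0 * g.total_w
    for v in (int(x) for x in rng.permutation(n)):
        if frozen[v] or sub_size[sub[v]] != 1:
            continue
        kv = g.strength[v]
        wts = defaultdict(float)
        for u, w in g.adj[v].items():
            if memb[u] == memb[v] and sub[u] != sub[v]:
                wts[sub[u]] += w
        best_s, best_gain = sub[v], 0.0
        for s in sorted(wts):
            # moving from a singleton: the stay term is exactly zero
            gain = wts[s] - gamma * kv * subK[s] / m2
            if gain > best_gain + _EPS:
                best_s, best_gain = s, gain
        if best_s != sub[v]:
            subK[best_s] += kv
            sub_size[best_s] += 1
            sub_size[sub[v]] -= 1
            subK[sub[v]] -= kv
            sub[v] = best_s
    return sub


def _aggregate(g: _Graph, memb, sub, frozen):
    """Collapse refined subcommunities into super-nodes."""
    uniq = {}
    for v in range(g.n):
        if sub[v] not in uniq:
            uniq[sub[v]] = len(uniq)
    S = len(uniq)
    node_of = np.array([uniq[sub[v]] for v in range(g.n)])
    adj = [dict() for _ in range(S)]
    self_w = [0.0] * S
    for v in range(g.n):
        a = node_of[v]
        self_w[a] += g.self_w[v]
        for u, w in g.adj[v].items():
            if u > v:
                b = node_of[u]
                if a == b:
                    self_w[a] += w
                else:
                    adj[a][b] = adj[a].get(b, 0.0) + w
                    adj[b][a] = adj[b].get(a, 0.0) + w
    new_memb = np.zeros(S, dtype=int)
    new_frozen = np.zeros(S, dtype=bool)
    for v in range(g.n):
        new_memb[node_of[v]] = memb[v]
        new_frozen[node_of[v]] |= frozen[v]
    return _Graph(S, adj, self_w), new_memb, new_frozen, node_of


def _leiden_once(graph: NeighborGraph, init_memb, frozen, gamma, seed, max_levels):
    rng = np.random.default_rng(seed)
    g = _Graph.from_neighbor_graph(graph)
    memb = np.asarray(init_memb, dtype=int).copy()
    frz = np.asarray(frozen, dtype=bool).copy()
    flat = np.arange(graph.n_cells)  # original node -> current super-node
    result = memb[flat].copy()
    for _ in range(max_levels):
        moved = _local_move(g, memb, frz, gamma, rng)
        result = memb[flat]
        sub = _refine(g, memb, frz, gamma, rng)
        g2, memb2, frz2, node_of = _aggregate(g, memb, sub, frz)
        if g2.n == g.n and not moved:
            break
        if g2.n == g.n:
            g, memb, frz = g2, memb2, frz2
            flat = node_of[flat]
            continue
        g, memb, frz = g2, memb2, frz2
        flat = node_of[flat]
    return result


def _run_leiden(graph: NeighborGraph, init: Partition, p: ClusterParams) -> Partition:
    if graph.n_cells == 0:
        raise ParameterError("empty graph")
    if len(init) != graph.n_cells:
        raise ParameterError(
            f"initial partition length {len(init)} != {graph.n_cells} nodes")
    # tiny graphs get a wider multi-start: restarts are cheap there and the
    # landscape has proportionally more attraction basins per node
    n_restarts = max(p.n_restarts, 48) if graph.n_cells <= 64 else p.n_restarts
    seeds = np.random.SeedSequence(p.seed).generate_state(max(1, n_restarts))
    n = graph.n_cells
    free = ~init.frozen
    best_labels, best_q = None, -np.inf
    for r, s in enumerate(seeds):
        s = int(s) % (2**31)
        start = init.labels.copy()
        if r % 3 == 1:
            # diversify: unfrozen nodes restart as singletons
            start[free] = init.labels.max() + 1 + np.arange(int(free.sum()))
        elif r % 3 == 2:
            # diversify: unfrozen nodes restart from a random coarse labeling
            rr = np.random.default_rng(s)
            start[free] = init.labels.max() + 1 + rr.integers(
                0, max(2, init.n_clusters), int(free.sum()))
        labels = _leiden_once(graph, start, init.frozen, p.resolution,
                              s, p.max_iterations)
        q = partition_quality(graph, labels, p.resolution)
        if q > best_q + _EPS:
            best_labels, best_q = labels, q
    part, _ = canonicalize(Partition(best_labels, init.frozen.copy()))
    return part


def leiden(graph: NeighborGraph, p: ClusterParams | None = None) -> Partition:
    """Unconstrained Leiden from a singleton initialization."""
    p = p or ClusterParams()
    init = Partition(np.arange(graph.n_cells), np.zeros(graph.n_cells, dtype=bool))
    return _run_leiden(graph, init, p)


def leiden_semisupervised(graph: NeighborGraph, init: Partition,
                          p: ClusterParams | None = None) -> Partition:
    """Leiden constrained by the frozen mask of ``init``.

    Frozen cells keep their initial community for the whole run: frozen
    cells sharing an initial label stay together, frozen cells with
    different initial labels stay apart, and unfrozen cells may move freely
    (including into frozen communities).  Quality never decreases across
    iterations given the constraints.
    """
    p = p or ClusterParams()
    if len(init.frozen) != graph.n_cells:
        raise ParameterError("frozen mask length mismatch with graph")
    return _run_leiden(graph, init, p)


def ari(a: Partition | np.ndarray, b: Partition | np.ndarray) -> float:
    """Adjusted Rand index between two labelings (contingency closed form)."""
    la = a.labels if isinstance(a, Partition) else np.asarray(a)
    lb = b.labels if isinstance(b, Partition) else np.asarray(b)
    if len(la) != len(lb):
        raise ParameterError(f"length mismatch: {len(la)} vs {len(lb)}")
    return float(adjusted_rand_score(la, lb))
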