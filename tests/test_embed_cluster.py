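import itertools

import numpy as np
import pytest

from scassign.core_data import AnnotatedMatrix, NeighborGraph, Partition
from scassign.embed_cluster import (ClusterParams, ReductionParams, ari,
                                    build_knn_graph, leiden,
                                    leiden_semisupervised, partition_quality,
                                    reduce_pca, reduce_umap)
from scassign.errors import ParameterError
from scassign.fixtures import (bruteforce_best_partition, constraints_satisfied,
                               small_graph_family)


def _annmat(x):
    return AnnotatedMatrix(x, [f"c{i}" for i in range(x.shape[0])],
                           [f"g{j}" for j in range(x.shape[1])])


class TestPCA:
    def test_exact_low_rank_reconstruction(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(30, 2)) @ rng.normal(size=(2, 8))  # rank 2
        m = reduce_pca(_annmat(x), ReductionParams(n_components=2, seed=0))
        emb = m.embeddings["reduced"]
        # rank-2 data: 2 components capture everything, distances preserved
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(emb), pdist(x - x.mean(0)), atol=1e-8)

    def test_explained_variance_nonincreasing(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(50, 10)) * np.arange(1, 11)
        m = reduce_pca(_annmat(x), ReductionParams(n_components=5, seed=0))
        var = m.embeddings["reduced"].var(axis=0)
        assert np.all(np.diff(var) <= 1e-9)

    def test_first_component_matches_analytic_eigenvector(self):
        # 3 points in 2-D: covariance eigendecomposition by hand
        x = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        m = reduce_pca(_annmat(x), ReductionParams(n_components=1, seed=0))
        emb = m.embeddings["reduced"][:, 0]
        # principal axis is (1,1)/sqrt(2); projections of centered points
        expected = (x - x.mean(0)) @ (np.array([1, 1]) / np.sqrt(2))
        assert np.allclose(emb, expected, atol=1e-8) or \
            np.allclose(emb, -expected, atol=1e-8)

    def test_too_many_components_reports_maximum(self):
        x = np.zeros((4, 3))
        with pytest.raises(ParameterError, match="3"):
            reduce_pca(_annmat(x), ReductionParams(n_components=10, seed=0))


class TestUMAP:
    def test_shapes_and_determinism(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(60, 12))
        m = _annmat(x)
        p = ReductionParams(seed=11)
        a = reduce_umap(m, p, key="u2", n_dims=2, n_neighbors=10)
        b = reduce_umap(m, p, key="u2", n_dims=2, n_neighbors=10)
        assert a.embeddings["u2"].shape == (60, 2)
        assert np.array_equal(a.embeddings["u2"], b.embeddings["u2"])
        c = reduce_umap(m, p, key="u10", n_dims=10, n_neighbors=10)
        assert c.embeddings["u10"].shape == (60, 10)

    def test_too_few_cells_raises(self):
        x = np.zeros((5, 3))
        with pytest.raises(ParameterError):
            reduce_umap(_annmat(x), ReductionParams(seed=0), n_neighbors=15)


class TestKnnGraph:
    def test_three_equidistant_points(self):
        x = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])  # equilateral
        g = build_knn_graph(x, k=1)
        deg = g.degrees()
        # ties break to the lower index: 0->1, 1->0, 2->0
        assert g.edges == {(0, 1), (0, 2)}
        assert all(d >= 1 for d in deg)

    def test_two_blobs_no_cross_edges_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 0.1, size=(10, 3))
        b = rng.normal(50, 0.1, size=(10, 3)) + 100
        x = np.vstack([a, b])
        g = build_knn_graph(x, k=3)
        for i, j in g.edges:
            assert (i < 10) == (j < 10)
        # brute-force oracle over all pairwise distances
        d = ((x[:, None] - x[None]) ** 2).sum(-1)
        np.fill_diagonal(d, np.inf)
        expected = set()
        for i in range(20):
            for j in np.argsort(d[i], kind="stable")[:3]:
                expected.add((min(i, int(j)), max(i, int(j))))
        assert g.edges == expected

    def test_k_equals_n_minus_1_complete(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(6, 2))
        g = build_knn_graph(x, k=5)
        assert len(g.edges) == 15

    def test_k_too_large_raises(self):
        with pytest.raises(ParameterError):
            build_knn_graph(np.zeros((4, 2)), k=4)


class TestLeiden:
    def test_two_disjoint_triangles(self, two_triangles):
        p = leiden(two_triangles, ClusterParams(seed=1))
        assert p.n_clusters == 2
        assert len(set(p.labels[:3])) == 1 and len(set(p.labels[3:])) == 1

    def test_complete_graph_single_cluster(self):
        g = NeighborGraph(5, set(itertools.combinations(range(5), 2)), 4)
        p = leiden(g, ClusterParams(seed=1))
        assert p.n_clusters == 1

    def test_quality_at_least_singletons(self):
        rng = np.random.default_rng(5)
        edges = {(i, j) for i, j in itertools.combinations(range(12), 2)
                 if rng.random() < 0.3}
        g = NeighborGraph(12, edges, 3)
        p = leiden(g, ClusterParams(seed=2))
        assert partition_quality(g, p.labels) >= \
            partition_quality(g, np.arange(12)) - 1e-9

    def test_empty_graph_raises(self):
        with pytest.raises(ParameterError):
            leiden(NeighborGraph(0, set(), 1), ClusterParams(seed=0))

    def test_resolution_monotonicity(self):
        # connected random graph: resolution drives granularity from one
        # community (gamma -> 0) toward singletons (gamma -> inf)
        rng = np.random.default_rng(6)
        edges = {(i, j) for i, j in itertools.combinations(range(30), 2)
                 if rng.random() < 0.25}
        edges |= {(i, i + 1) for i in range(29)}  # ensure connectivity
        g = NeighborGraph(30, edges, 3)
        k_high = leiden(g, ClusterParams(seed=3, resolution=100.0)).n_clusters
        k_low = leiden(g, ClusterParams(seed=3, resolution=1e-4)).n_clusters
        assert k_high > k_low
        assert k_low == 1

    def test_matches_leidenalg_quality_on_blobs(self):
        """Independent cross-check against the reference Leiden library."""
        import igraph
        import leidenalg
        rng = np.random.default_rng(7)
        x = np.vstack([rng.normal(c * 20, 2, size=(60, 6)) for c in range(3)])
        g = build_knn_graph(x, 10)
        ours = leiden(g, ClusterParams(seed=4))
        G = igraph.Graph(n=g.n_cells, edges=list(g.edges))
        ref = leidenalg.find_partition(
            G, leidenalg.RBConfigurationVertexPartition,
            resolution_parameter=1.0, seed=4, n_iterations=-1)
        q_ours = partition_quality(g, ours.labels)
        q_ref = partition_quality(g, np.array(ref.membership))
        assert q_ours >= q_ref - 1e-9


class TestLeidenSemisupervised:
    def test_all_frozen_returns_init(self, two_triangles):
        init = Partition(np.array([0, 0, 1, 1, 2, 2]), np.ones(6, dtype=bool))
        p = leiden_semisupervised(two_triangles, init, ClusterParams(seed=0))
        assert ari(p, init) == 1.0

    def test_none_frozen_equivalent_to_leiden(self, two_triangles):
        init = Partition(np.array([0, 1, 2, 3, 4, 5]))
        p = leiden_semisupervised(two_triangles, init, ClusterParams(seed=9))
        q = leiden(two_triangles, ClusterParams(seed=9))
        assert ari(p, q) == 1.0

    def test_misplaced_unfrozen_member_moves_home(self):
        # two triangles joined by an edge; freeze one triangle, leave a
        # deliberately mislabeled member of the other triangle unfrozen
        g = NeighborGraph(6, {(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5),
                              (2, 3)}, 2)
        init = Partition(np.array([0, 0, 0, 0, 1, 1]),
                         np.array([True, True, True, False, False, False]))
        p = leiden_semisupervised(g, init, ClusterParams(seed=1))
        assert p.labels[3] == p.labels[4] == p.labels[5]
        assert p.labels[0] == p.labels[1] == p.labels[2]
        assert p.labels[0] != p.labels[3]
        labels, q = bruteforce_best_partition(g, 1.0, init.labels, init.frozen)
        assert partition_quality(g, p.labels) == pytest.approx(q)

    def test_frozen_mask_mismatch_raises(self, two_triangles):
        init = Partition(np.zeros(4, dtype=int))
        with pytest.raises(ParameterError):
            leiden_semisupervised(two_triangles, init, ClusterParams(seed=0))

    def test_constraints_hold_on_random_graphs(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            n = int(rng.integers(8, 20))
            edges = {(i, j) for i, j in itertools.combinations(range(n), 2)
                     if rng.random() < 0.3}
            if not edges:
                continue
            g = NeighborGraph(n, edges, 3)
            init = Partition(rng.integers(0, 3, n), rng.random(n) < 0.4)
            p = leiden_semisupervised(g, init, ClusterParams(seed=5))
            assert constraints_satisfied(p.labels, init.labels, init.frozen)

    def test_constraint_satisfying_optimum_matches_unconstrained(self, two_triangles):
        # freezing the true communities should not cost any quality
        init = Partition(np.array([0, 0, 0, 1, 1, 1]), np.ones(6, dtype=bool))
        p = leiden_semisupervised(two_triangles, init, ClusterParams(seed=2))
        q_con = partition_quality(two_triangles, p.labels)
        q_unc = partition_quality(two_triangles,
                                  leiden(two_triangles, ClusterParams(seed=2)).labels)
        assert q_con == pytest.approx(q_unc)


class TestAri:
    def test_identity_and_permutation_invariance(self):
        a = Partition(np.array([0, 0, 1, 1, 2]))
        b = Partition(np.array([5, 5, 9, 9, 7]))
        assert ari(a, a) == 1.0
        assert ari(a, b) == 1.0

    def test_hand_computed_value(self):
        # contingency closed form for [0,0,1,1] vs [0,1,0,1] gives -0.5
        assert ari(np.array([0, 0, 1, 1]), np.array([0, 1, 0, 1])) == \
            pytest.approx(-0.5)

    def test_length_mismatch_raises(self):
        with pytest.raises(ParameterError):
            ari(np.array([0, 1]), np.array([0, 1, 2]))
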