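"""SNN graph, Louvain, partition metric, resolution search, sub-clustering.

The KNN/SNN constructions are checked against brute-force oracles; Louvain
is checked against exhaustive partition enumeration on small graphs; the
metric against hand computations.
"""

import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

import isrpipe as ip
from isrpipe.cluster import Partition, SnnGraph, SubclusterConfig


def graph_from_dense(A, prune=1 / 15):
    A = np.asarray(A, dtype=float)
    return SnnGraph(
        node_ids=[str(i) for i in range(A.shape[0])],
        adjacency=sp.csr_matrix(A),
        k=1,
        prune_cutoff=prune,
    )


def two_triangles():
    A = np.zeros((6, 6))
    for a, b in [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)]:
        A[a, b] = A[b, a] = 1.0
    return graph_from_dense(A)


def set_partitions(items):
    items = list(items)
    if len(items) == 1:
        yield [items]
        return
    first = items[0]
    for smaller in set_partitions(items[1:]):
        for n, subset in enumerate(smaller):
            yield smaller[:n] + [[first] + subset] + smaller[n + 1:]
        yield [[first]] + smaller


def best_partition_by_enumeration(graph, resolution):
    n = graph.n_nodes
    best_q, best_labels = -np.inf, None
    for part in set_partitions(range(n)):
        labels = np.empty(n, dtype=int)
        for c, block in enumerate(part):
            labels[block] = c
        q = ip.modularity(graph, labels, resolution)
        if q > best_q:
            best_q, best_labels = q, labels
    return best_q, best_labels


class TestKnn:
    def test_k_formula_caps_at_750(self):
        rng = np.random.default_rng(0)
        nb = ip.build_knn(rng.random((800, 3)), k_cap=750)
        assert nb.shape == (800, 751)

    def test_k_formula_small_n(self):
        rng = np.random.default_rng(1)
        nb = ip.build_knn(rng.random((100, 3)), k_cap=750)
        assert nb.shape == (100, 100)  # K = 99 -> every other cell + self
        for i in range(100):
            assert np.array_equal(np.sort(nb[i]), np.arange(100))

    def test_neighbor_sets_include_self(self):
        rng = np.random.default_rng(2)
        nb = ip.build_knn(rng.random((30, 4)), k_cap=5)
        for i in range(30):
            assert i in nb[i]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        X = rng.random((20, 5))
        k = 6
        nb = ip.build_knn(X, k_cap=k)
        d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        for i in range(20):
            order = sorted(range(20), key=lambda j: (d[i, j], j))
            expected = sorted([j for j in order if j != i][:k] + [i])
            assert np.array_equal(nb[i], expected)

    def test_single_cell_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            ip.build_knn(np.zeros((1, 3)), k_cap=5)


class TestSnn:
    def test_two_cells_k1_full_jaccard(self):
        nb = np.array([[0, 1], [0, 1]])
        g = ip.build_snn_jaccard(nb)
        assert g.adjacency.nnz == 2  # one undirected edge
        assert g.adjacency[0, 1] == pytest.approx(1.0)

    def test_disjoint_sets_no_edge(self):
        nb = np.array([[0, 1], [0, 1], [2, 3], [2, 3]])
        g = ip.build_snn_jaccard(nb)
        assert g.adjacency[0, 2] == 0
        assert g.adjacency[1, 3] == 0

    def test_matches_brute_force_pairwise_jaccard(self):
        rng = np.random.default_rng(4)
        X = rng.random((50, 6))
        nb = ip.build_knn(X, k_cap=10)
        g = ip.build_snn_jaccard(nb, prune_cutoff=1 / 15)
        sets = [set(row) for row in nb]
        for i in range(50):
            for j in range(i + 1, 50):
                inter = len(sets[i] & sets[j])
                union = len(sets[i] | sets[j])
                jacc = inter / union
                expected = jacc if jacc >= 1 / 15 else 0.0
                assert g.adjacency[i, j] == pytest.approx(expected)

    def test_pruning_and_symmetry_invariants(self):
        rng = np.random.default_rng(5)
        nb = ip.build_knn(rng.random((40, 4)), k_cap=8)
        g = ip.build_snn_jaccard(nb, prune_cutoff=0.2)
        adj = g.adjacency
        assert (abs(adj - adj.T)).nnz == 0
        assert adj.diagonal().sum() == 0
        assert adj.data.min() >= 0.2
        assert adj.data.max() <= 1.0


class TestLouvain:
    def test_two_disconnected_triangles(self):
        part = ip.louvain(two_triangles(), resolution=1.0, seed=0)
        assert part.n_communities == 2
        labels = part.labels
        assert labels[0] == labels[1] == labels[2]
        assert labels[3] == labels[4] == labels[5]

    def test_single_node(self):
        g = graph_from_dense(np.zeros((1, 1)))
        part = ip.louvain(g, resolution=1.0, seed=0)
        assert part.n_communities == 1
        assert part.modularity == 0.0

    @pytest.mark.parametrize("trial", range(5))
    def test_attains_enumeration_optimum(self, trial):
        """Best-of-10-seed Louvain reaches the exhaustive Q(r) maximum."""
        rng = np.random.default_rng(100 + trial)
        n = int(rng.integers(5, 9))
        A = np.triu(
            (rng.random((n, n)) < 0.5) * rng.random((n, n)), 1
        )
        g = graph_from_dense(A + A.T)
        for resolution in (0.5, 1.0, 1.5):
            best_q, _ = best_partition_by_enumeration(g, resolution)
            louv_q = max(
                ip.louvain(g, resolution=resolution, seed=s).modularity
                for s in range(10)
            )
            assert louv_q == pytest.approx(best_q, abs=1e-9)

    def test_beats_trivial_partitions(self):
        rng = np.random.default_rng(6)
        A = np.triu((rng.random((30, 30)) < 0.2) * rng.random((30, 30)), 1)
        g = graph_from_dense(A + A.T)
        part = ip.louvain(g, resolution=1.0, seed=0)
        singletons = np.arange(30)
        one = np.zeros(30, dtype=int)
        assert part.modularity >= ip.modularity(g, singletons, 1.0) - 1e-12
        assert part.modularity >= ip.modularity(g, one, 1.0) - 1e-12

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(7)
        A = np.triu((rng.random((40, 40)) < 0.3) * rng.random((40, 40)), 1)
        g = graph_from_dense(A + A.T)
        a = ip.louvain(g, resolution=0.8, seed=3)
        b = ip.louvain(g, resolution=0.8, seed=3)
        assert np.array_equal(a.labels, b.labels)


class TestPartitionMetric:
    def test_two_cliques_partitioned_correctly(self):
        labels = np.array([0, 0, 0, 1, 1, 1])
        part = Partition(labels=labels, resolution=1.0, modularity=0.0)
        assert ip.partition_metric(two_triangles(), part) == pytest.approx(1.0)

    def test_all_singletons(self):
        labels = np.arange(6)
        part = Partition(labels=labels, resolution=1.0, modularity=0.0)
        # unifiability 1 (singletons), isolability 0 (all weight cut)
        assert ip.partition_metric(two_triangles(), part) == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        A = 1.0 - np.eye(5)
        g = graph_from_dense(A)
        part = Partition(labels=np.zeros(5, int), resolution=1.0,
                         modularity=0.0)
        assert ip.partition_metric(g, part) == pytest.approx(1.0)

    def test_bounded_in_unit_interval(self):
        rng = np.random.default_rng(8)
        A = np.triu((rng.random((20, 20)) < 0.4) * rng.random((20, 20)), 1)
        g = graph_from_dense(A + A.T)
        for seed in range(3):
            labels = rng.integers(0, 4, 20)
            _, labels = np.unique(labels, return_inverse=True)
            part = Partition(labels=labels, resolution=1.0, modularity=0.0)
            assert 0.0 <= ip.partition_metric(g, part) <= 1.0


class TestResolutionSearch:
    def test_default_grid_has_48_points(self):
        from isrpipe.cluster import default_resolution_grid

        grid = default_resolution_grid()
        assert grid.size == 48
        assert grid[0] == pytest.approx(0.05)
        assert grid[-1] == pytest.approx(1.225)
        assert np.allclose(np.diff(grid), 0.025)

    def test_two_cliques_selected_with_unit_metric(self):
        scan = ip.resolution_search(two_triangles(), seed=0)
        part = scan.selected_partition
        assert part.n_communities == 2
        assert scan.metrics[scan.selected_index] == pytest.approx(1.0)

    def test_tie_resolves_to_smallest_resolution(self):
        # disconnected cliques: every resolution that finds them scores 1.0
        scan = ip.resolution_search(two_triangles(), seed=0)
        maxima = np.flatnonzero(
            scan.metrics == scan.metrics[scan.selected_index]
        )
        assert scan.selected_index == maxima[0]


class TestIterativeSubcluster:
    @staticmethod
    def _normalized_from_sim(sim_cfg):
        counts, truth, _, _ = ip.simulate_droplets(sim_cfg)
        filt = ip.BarcodeFilter().fit_transform(counts)
        norm = ip.normalize_counts(filt)
        types = truth.barcodes.loc[norm.barcode_ids, "cell_type"].to_numpy()
        return norm, types

    def test_homogeneous_single_type_never_splits(self):
        cfg = ip.CellSimConfig(
            n_cell_types=1, cells_per_type=120, n_genes=300,
            markers_per_type=10, n_empty_droplets=300,
            n_signature_genes=20, basal_signature_types=(0,),
            genotype_signature_types=(0,), seed=11,
        )
        norm, _ = self._normalized_from_sim(cfg)
        seed_part = Partition(
            labels=np.zeros(norm.n_barcodes, int), resolution=0.5,
            modularity=0.0,
        )
        sub = SubclusterConfig(k_cap=30, min_cells=10)
        out = ip.iterative_subcluster(norm, seed_part, config=sub, seed=0)
        assert out.n_clusters == 1
        assert set(out.hierarchical) == {"0"}

    def test_recovers_hidden_substructure(self):
        """A seed partition that merges two planted types is split once,
        giving three leaves and a depth-2 hierarchy."""
        cfg = ip.CellSimConfig(
            n_cell_types=3, cells_per_type=100, n_genes=400,
            markers_per_type=12, n_empty_droplets=300,
            n_signature_genes=20, basal_signature_types=(0,),
            genotype_signature_types=(0,), seed=12,
        )
        norm, types = self._normalized_from_sim(cfg)
        names = sorted(set(types))
        # merge the 2nd and 3rd types into one seed cluster
        labels = np.where(types == names[0], 0, 1)
        seed_part = Partition(labels=labels, resolution=0.5, modularity=0.0)
        sub = SubclusterConfig(k_cap=30, min_cells=10)
        out = ip.iterative_subcluster(norm, seed_part, config=sub, seed=0)
        assert out.n_clusters == 3
        depths = {h.count(".") for h in out.hierarchical}
        assert depths == {0, 1}  # untouched leaf plus two children
        assert adjusted_rand_score(types, out.final) >= 0.9

    def test_deterministic_rerun(self):
        cfg = ip.CellSimConfig(
            n_cell_types=2, cells_per_type=80, n_genes=300,
            markers_per_type=10, n_empty_droplets=200,
            n_signature_genes=20, basal_signature_types=(0,),
            genotype_signature_types=(0,), seed=13,
        )
        norm, types = self._normalized_from_sim(cfg)
        seed_part = Partition(
            labels=np.zeros(norm.n_barcodes, int), resolution=0.5,
            modularity=0.0,
        )
        sub = SubclusterConfig(k_cap=30, min_cells=10)
        a = ip.iterative_subcluster(norm, seed_part, config=sub, seed=5)
        b = ip.iterative_subcluster(norm, seed_part, config=sub, seed=5)
        assert a.hierarchical == b.hierarchical


def test_default_sim_ari(default_sim, default_run):
    """Final leaves recover the planted cell types (ARI >= 0.9)."""
    assignment = default_run["assignment"]
    truth = default_sim["truth"]
    types = truth.barcodes.loc[assignment.barcode_ids, "cell_type"].to_numpy()
    assert adjusted_rand_score(types, assignment.final) >= 0.9
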