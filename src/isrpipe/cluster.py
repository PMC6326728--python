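"""SNN-graph construction and iterative Louvain clustering.

Cells are connected by a shared-nearest-neighbor (SNN) graph: each cell's
neighbor set is itself plus its K = min(K_cap, n_cells - 1) Euclidean
nearest neighbors in PC space, edge weights are Jaccard indices of neighbor
sets, and edges with Jaccard similarity below a prune cutoff (default 1/15)
are removed. Louvain community detection is run over a resolution grid
(default 0.05 to 1.225 in steps of 0.025) and the resolution maximizing the
mean unifiability/isolability partition metric is selected. The procedure
is then repeated on each cluster's cells alone (re-selecting variable genes
and re-embedding), splitting a cluster whenever the sub-partition has at
least two sufficiently large communities and does not lower the cluster's
metric contribution on the parent graph; convergence is reached when no
cluster can be broken down further.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

import igraph as ig
import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.metrics import pairwise_distances

from .containers import NormalizedMatrix
from .embed import Embedding, compute_pca, select_variable_genes

logger = logging.getLogger(__name__)

__all__ = [
    "SnnGraph",
    "Partition",
    "ResolutionScan",
    "ClusterAssignment",
    "SubclusterConfig",
    "build_knn",
    "build_snn_jaccard",
    "louvain",
    "modularity",
    "partition_metric",
    "default_resolution_grid",
    "resolution_search",
    "iterative_subcluster",
    "SnnLouvainClusterer",
]

DEFAULT_PRUNE_CUTOFF = 1.0 / 15.0
DEFAULT_K_CAP = 750


@dataclass
class SnnGraph:
    """Weighted undirected SNN graph over cells.

    ``adjacency`` is a symmetric sparse matrix of Jaccard weights in (0, 1]
    with zero diagonal; every stored edge weight is >= ``prune_cutoff``.
    """

    node_ids: list[str]
    adjacency: sp.csr_matrix
    k: int
    prune_cutoff: float = DEFAULT_PRUNE_CUTOFF

    def __post_init__(self) -> None:
        self.adjacency = sp.csr_matrix(self.adjacency)
        n = len(self.node_ids)
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edge_arrays(self):
        """(i, j, w) for each undirected edge once (i < j)."""
        coo = sp.triu(self.adjacency, k=1).tocoo()
        return coo.row, coo.col, coo.data

    def total_weight(self) -> float:
        return float(sp.triu(self.adjacency, k=1).sum())


@dataclass
class Partition:
    """Community labels (contiguous from 0) with resolution and modularity."""

    labels: np.ndarray
    resolution: float
    modularity: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        uniq = np.unique(self.labels)
        if self.labels.size and not np.array_equal(uniq, np.arange(uniq.size)):
            raise ValueError("labels must be contiguous from 0")

    @property
    def n_communities(self) -> int:
        return int(self.labels.max()) + 1 if self.labels.size else 0


@dataclass
class ResolutionScan:
    resolutions: np.ndarray
    metrics: np.ndarray
    partitions: list[Partition]
    selected_index: int

    @property
    def selected_resolution(self) -> float:
        return float(self.resolutions[self.selected_index])

    @property
    def selected_partition(self) -> Partition:
        return self.partitions[self.selected_index]


@dataclass
class ClusterAssignment:
    """Hierarchical cluster labels per cell.

    ``hierarchical`` holds dot-separated paths (e.g. ``"3.1"``); ``final``
    holds flat integer labels, contiguous from 0, ordered by hierarchical
    label.
    """

    barcode_ids: list[str]
    hierarchical: list[str]
    final: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if len(self.hierarchical) != len(self.barcode_ids):
            raise ValueError("one hierarchical label per barcode required")
        if self.final is None:
            leaves = sorted(
                set(self.hierarchical),
                key=lambda s: [int(p) for p in s.split(".")],
            )
            lookup = {leaf: i for i, leaf in enumerate(leaves)}
            self.final = np.array(
                [lookup[h] for h in self.hierarchical], dtype=int
            )
        else:
            self.final = np.asarray(self.final, dtype=int)

    @property
    def leaf_labels(self) -> list[str]:
        seen = {}
        for h, f in zip(self.hierarchical, self.final):
            seen[int(f)] = h
        return [seen[i] for i in sorted(seen)]

    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for h in self.hierarchical:
            out[h] = out.get(h, 0) + 1
        return out

    def cells_of(self, final_label: int) -> np.ndarray:
        return np.flatnonzero(self.final == final_label)

    @property
    def n_clusters(self) -> int:
        return int(self.final.max()) + 1 if len(self.final) else 0


def build_knn(embedding: Embedding | np.ndarray, k_cap: int = DEFAULT_K_CAP) -> np.ndarray:
    """Neighbor index sets: each cell plus its K nearest cells.

    K = min(k_cap, n_cells - 1); Euclidean distance in PC space; distance
    ties broken toward the lower cell index. Returns an (n_cells, K+1)
    integer array whose rows are sorted neighbor index sets (self included).
    """
    coords = embedding.coordinates if isinstance(embedding, Embedding) else embedding
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 cells for a KNN graph")
    k = min(k_cap, n - 1)
    neighbors = np.empty((n, k + 1), dtype=np.int64)
    chunk = max(1, int(2e8 // (8 * n)))
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d = pairwise_distances(coords[start:stop], coords)
        # stable argsort on distance: equal distances keep index order,
        # which is exactly the lower-index tie-break rule
        order = np.argsort(d, axis=1, kind="stable")
        for r in range(stop - start):
            own = start + r
            row = order[r, : k + 2]
            sel = row[row != own][:k]
            neighbors[own] = np.sort(np.append(sel, own))
    return neighbors


def build_snn_jaccard(
    neighbors: np.ndarray,
    prune_cutoff: float = DEFAULT_PRUNE_CUTOFF,
    node_ids: list[str] | None = None,
) -> SnnGraph:
    """Jaccard SNN graph from neighbor sets, pruning weights < cutoff."""
    neighbors = np.asarray(neighbors)
    n, size = neighbors.shape
    rows = np.repeat(np.arange(n), size)
    incidence = sp.csr_matrix(
        (np.ones(rows.size, dtype=np.int32), (rows, neighbors.ravel())),
        shape=(n, n),
    )
    inter = (incidence @ incidence.T).tocoo()
    mask = inter.row < inter.col
    i, j, shared = inter.row[mask], inter.col[mask], inter.data[mask].astype(float)
    union = 2.0 * size - shared
    jacc = shared / union
    keep = jacc >= prune_cutoff
    i, j, jacc = i[keep], j[keep], jacc[keep]
    adj = sp.csr_matrix(
        (np.concatenate([jacc, jacc]),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    )
    if node_ids is None:
        node_ids = [str(x) for x in range(n)]
    return SnnGraph(
        node_ids=node_ids, adjacency=adj, k=size - 1, prune_cutoff=prune_cutoff
    )


def _to_igraph_permuted(graph: SnnGraph, seed: int):
    """Seed-permuted igraph copy (cached per seed).

    igraph's multilevel sweep follows vertex and edge insertion order, so
    the seed permutes vertex ids and shuffles the edge list to randomize the
    local-moving order. One scan reuses a single seed, so the conversion is
    cached per (graph, seed).
    """
    cache = getattr(graph, "_ig_seed_cache", None)
    if cache is None:
        cache = graph._ig_seed_cache = {}
    if seed not in cache:
        i, j, w = graph.edge_arrays()
        rng = np.random.default_rng(seed)
        perm = rng.permutation(graph.n_nodes)
        order = rng.permutation(i.size)
        g = ig.Graph(
            n=graph.n_nodes,
            edges=np.column_stack([perm[i][order], perm[j][order]]).tolist(),
        )
        g.es["weight"] = w[order].tolist()
        cache[seed] = (g, perm)
    return cache[seed]


def modularity(graph: SnnGraph, labels: np.ndarray, resolution: float) -> float:
    """Resolution-scaled Newman modularity of a labeling.

    Q(r) = sum_c [ W_in(c)/W_tot - r * (S_c / (2 W_tot))^2 ], where W_in is
    the internal edge weight of community c, S_c its summed weighted degree
    and W_tot the total edge weight.
    """
    labels = np.asarray(labels)
    i, j, w = graph.edge_arrays()
    w_tot = w.sum()
    if w_tot == 0:
        return 0.0
    n_comm = labels.max() + 1
    w_in = np.zeros(n_comm)
    internal = labels[i] == labels[j]
    np.add.at(w_in, labels[i[internal]], w[internal])
    degree = np.asarray(graph.adjacency.sum(axis=1)).ravel()
    s = np.zeros(n_comm)
    np.add.at(s, labels, degree)
    return float(np.sum(w_in / w_tot - resolution * (s / (2 * w_tot)) ** 2))


def _relabel_contiguous(membership) -> np.ndarray:
    labels = np.asarray(membership, dtype=int)
    _, out = np.unique(labels, return_inverse=True)
    return out


def louvain(graph: SnnGraph, resolution: float = 1.0, seed: int = 0) -> Partition:
    """Louvain community detection at a given resolution.

    Greedy local moving plus graph aggregation repeated to a fixed point
    (igraph's multilevel implementation), maximizing the resolution-scaled
    modularity; the node sweep order is randomized by ``seed``.
    """
    if graph.n_nodes == 0:
        raise ValueError("empty graph")
    if graph.adjacency.nnz == 0:
        labels = np.arange(graph.n_nodes)
        return Partition(labels=labels, resolution=resolution, modularity=0.0)
    g, perm = _to_igraph_permuted(graph, seed)
    ig.set_random_number_generator(random.Random(seed))
    comm = g.community_multilevel(weights="weight", resolution=resolution)
    # label of original vertex v is the permuted vertex perm[v]'s community
    membership = np.asarray(comm.membership)[perm]
    labels = _relabel_contiguous(membership)
    return Partition(
        labels=labels,
        resolution=resolution,
        modularity=modularity(graph, labels, resolution),
    )


def _community_contributions(graph: SnnGraph, labels: np.ndarray) -> np.ndarray:
    """Per-community (unifiability + isolability) / 2 on ``graph``."""
    labels = np.asarray(labels)
    n_comm = labels.max() + 1
    i, j, w = graph.edge_arrays()
    internal = labels[i] == labels[j]
    w_in = np.zeros(n_comm)
    np.add.at(w_in, labels[i[internal]], w[internal])
    w_cut = np.zeros(n_comm)
    ext_i, ext_j, ext_w = i[~internal], j[~internal], w[~internal]
    np.add.at(w_cut, labels[ext_i], ext_w)
    np.add.at(w_cut, labels[ext_j], ext_w)
    sizes = np.bincount(labels, minlength=n_comm).astype(float)

    pairs = sizes * (sizes - 1) / 2
    unif = np.ones(n_comm)
    multi = sizes >= 2
    unif[multi] = w_in[multi] / pairs[multi]
    incident = w_in + w_cut
    iso = np.ones(n_comm)
    touched = incident > 0
    iso[touched] = 1.0 - w_cut[touched] / incident[touched]
    return (unif + iso) / 2.0


def partition_metric(graph: SnnGraph, partition: Partition | np.ndarray) -> float:
    """Mean unifiability/isolability score of a partition, in [0, 1].

    Unifiability of a community is its weighted internal edge density
    (1 for singletons); isolability is the complement of the fraction of
    incident edge weight that leaves the community (1 for isolated
    communities). The metric is the mean over communities of the average of
    the two. It penalizes over-merging through low density and
    over-splitting through low isolability.
    """
    labels = partition.labels if isinstance(partition, Partition) else partition
    return float(_community_contributions(graph, np.asarray(labels)).mean())


def default_resolution_grid(
    start: float = 0.05, stop: float = 1.225, step: float = 0.025
) -> np.ndarray:
    n = int(round((stop - start) / step)) + 1
    return start + step * np.arange(n)


def resolution_search(
    graph: SnnGraph,
    grid: np.ndarray | None = None,
    seed: int = 0,
) -> ResolutionScan:
    """Louvain across a resolution grid; select the metric-maximizing one.

    Ties on the metric resolve toward the smallest resolution.
    """
    if grid is None:
        grid = default_resolution_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("resolution grid is empty")
    partitions = []
    metrics = np.empty(grid.size)
    for idx, r in enumerate(grid):
        part = louvain(graph, resolution=float(r), seed=seed)
        partitions.append(part)
        metrics[idx] = partition_metric(graph, part)
    best = int(np.argmax(metrics))  # argmax returns first maximum -> smallest r
    return ResolutionScan(
        resolutions=grid, metrics=metrics, partitions=partitions,
        selected_index=best,
    )


@dataclass
class SubclusterConfig:
    """Knobs of the iterative clustering procedure."""

    k_cap: int = DEFAULT_K_CAP
    prune_cutoff: float = DEFAULT_PRUNE_CUTOFF
    resolution_grid: np.ndarray | None = None
    min_cells: int = 10
    n_pcs: int = 50
    n_bins: int = 20
    z_cutoff: float = 1.0
    mean_bounds: tuple[float, float] = (0.0125, 8.0)
    max_depth: int = 10


def _sub_embedding(
    normalized: NormalizedMatrix, cells: np.ndarray, config: SubclusterConfig,
    seed: int,
) -> np.ndarray | None:
    """Re-select variable genes and re-embed a subset of cells."""
    sub = NormalizedMatrix(
        gene_ids=normalized.gene_ids,
        barcode_ids=[normalized.barcode_ids[c] for c in cells],
        values=normalized.values[:, cells],
    )
    try:
        genes = select_variable_genes(
            sub, n_bins=config.n_bins,
            z_cutoff=config.z_cutoff, mean_bounds=config.mean_bounds,
        )
        emb = compute_pca(sub, genes, n_pcs=config.n_pcs, random_state=seed)
    except ValueError as exc:
        logger.info("subset of %d cells not embeddable: %s", len(cells), exc)
        return None
    return emb.coordinates


def iterative_subcluster(
    normalized: NormalizedMatrix,
    seed_partition: Partition,
    config: SubclusterConfig | None = None,
    seed: int = 0,
    root_graph: SnnGraph | None = None,
) -> ClusterAssignment:
    """Recursively re-cluster each cluster until none can be broken down.

    Each leaf with >= 2 * min_cells cells is re-analyzed alone (variable
    genes, PCA, SNN, resolution search). A split is accepted when the
    selected sub-partition has >= 2 communities of size >= min_cells each
    and the mean metric contribution of the children, evaluated on the
    root SNN graph, is at least the leaf's own contribution. Leaves are
    processed in ascending label order; child labels extend the parent's
    with ``.i`` (1-based).
    """
    if config is None:
        config = SubclusterConfig()
    n = normalized.n_barcodes
    hier = [str(l) for l in seed_partition.labels]
    frontier = sorted(
        set(hier), key=lambda s: [int(p) for p in s.split(".")]
    )
    root_labels = np.asarray(seed_partition.labels)

    def contribution(cells: np.ndarray) -> float:
        if root_graph is None:
            return -np.inf  # no graph: accept any structurally valid split
        labels = np.zeros(n, dtype=int)
        labels[cells] = 1
        # contribution of the community formed by `cells` on the root graph
        return float(_community_contributions(root_graph, labels)[1])

    hier_arr = np.array(hier, dtype=object)
    depth = 1
    while frontier and depth <= config.max_depth:
        next_frontier: list[str] = []
        for leaf in frontier:
            cells = np.flatnonzero(hier_arr == leaf)
            if cells.size < 2 * config.min_cells:
                continue
            coords = _sub_embedding(normalized, cells, config, seed)
            if coords is None:
                continue
            neigh = build_knn(coords, k_cap=config.k_cap)
            graph = build_snn_jaccard(neigh, prune_cutoff=config.prune_cutoff)
            scan = resolution_search(graph, grid=config.resolution_grid, seed=seed)
            part = scan.selected_partition
            sizes = np.bincount(part.labels)
            if part.n_communities < 2 or (sizes < config.min_cells).any():
                continue
            if root_graph is not None:
                parent_contrib = contribution(cells)
                child_contribs = [
                    contribution(cells[part.labels == c])
                    for c in range(part.n_communities)
                ]
                if np.mean(child_contribs) < parent_contrib:
                    logger.info(
                        "rejecting split of %s: metric contribution "
                        "%.4f -> %.4f", leaf, parent_contrib,
                        float(np.mean(child_contribs)),
                    )
                    continue
            for c in range(part.n_communities):
                child = f"{leaf}.{c + 1}"
                hier_arr[cells[part.labels == c]] = child
                next_frontier.append(child)
            logger.info("split cluster %s into %d sub-clusters", leaf,
                        part.n_communities)
        frontier = sorted(
            next_frontier, key=lambda s: [int(p) for p in s.split(".")]
        )
        depth += 1
    return ClusterAssignment(
        barcode_ids=normalized.barcode_ids,
        hierarchical=list(hier_arr),
    )


class SnnLouvainClusterer(ClusterMixin, BaseEstimator):
    """SNN/Louvain clustering over a resolution grid, sklearn-style.

    ``fit(X)`` takes a cells x PCs coordinate array, builds the KNN/Jaccard
    SNN graph and selects the metric-maximizing Louvain partition.

    Attributes
    ----------
    graph_ : SnnGraph
    scan_ : ResolutionScan
    labels_ : ndarray of shape (n_cells,)
    """

    def __init__(self, k_cap: int = DEFAULT_K_CAP,
                 prune_cutoff: float = DEFAULT_PRUNE_CUTOFF,
                 resolution_grid: np.ndarray | None = None,
                 random_state: int = 0):
        self.k_cap = k_cap
        self.prune_cutoff = prune_cutoff
        self.resolution_grid = resolution_grid
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        neighbors = build_knn(X, k_cap=self.k_cap)
        self.graph_ = build_snn_jaccard(
            neighbors, prune_cutoff=self.prune_cutoff
        )
        self.scan_ = resolution_search(
            self.graph_, grid=self.resolution_grid, seed=self.random_state
        )
        self.labels_ = self.scan_.selected_partition.labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_
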