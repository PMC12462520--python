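"""Spatial proximity graphs and graph-derived summaries.

A tissue image is represented as a binary, symmetric, self-loop-free
adjacency over cells: an edge connects two cells whose Euclidean distance
is strictly below a radius ``r`` (fixed pixel-equivalent units across
images). On top of this the module provides the degree histogram used by
the density models, the symmetrized kNN graph and spectral clustering used
by the self-supervision task, the feature-permutation control, and the
expression-correlation kNN graph.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.spatial import cKDTree

logger = logging.getLogger("tissuegraph")

DEGREE_BINS = 16  # degrees 0..14 plus one overflow bin for >14


@dataclass
class SpatialGraph:
    """Adjacency + node features + node metadata for one sample."""

    adjacency: sp.csr_matrix      # binary, symmetric, zero diagonal
    node_features: np.ndarray     # (n, d)
    cell_type: np.ndarray | None = None
    immune_flag: np.ndarray | None = None
    radius: float | None = None
    sample_id: str | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)


@dataclass
class ClusterAssignment:
    labels: np.ndarray            # cluster id per node, in [0, n_clusters)
    knn_adjacency: sp.csr_matrix
    k: int
    n_clusters: int


@dataclass
class CompositionTarget:
    """Normalized cell-type frequencies pooled over neighboring clusters."""

    cluster_id: int
    vector: np.ndarray
    valid: bool


def build_radius_graph(coords, r: float) -> sp.csr_matrix:
    """Binary adjacency with an edge iff distance < r (strict), no self-loops."""
    if r <= 0:
        raise ValueError("radius must be positive")
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n == 0:
        return sp.csr_matrix((0, 0))
    pairs = cKDTree(coords).query_pairs(r, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        pairs = pairs[d < r]  # query_pairs is <=; the definition is strict
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.array([], int)
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.array([], int)
    A = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return A


def degree_histogram(graph) -> np.ndarray:
    """Normalized histogram of node degrees: bins 0..14 plus an overflow bin."""
    A = graph.adjacency if isinstance(graph, SpatialGraph) else graph
    n = A.shape[0]
    if n == 0:
        raise ValueError("degree histogram of an empty graph is undefined")
    deg = np.asarray(A.sum(axis=1)).ravel().astype(int)
    hist = np.zeros(DEGREE_BINS)
    clipped = np.minimum(deg, DEGREE_BINS - 1)
    np.add.at(hist, clipped, 1.0)
    return hist / n


def build_knn_graph(coords, k: int) -> sp.csr_matrix:
    """Undirected kNN graph: edge iff i in kNN(j) or j in kNN(i).

    Distance ties are broken in favor of the lower node index.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of nodes {n}")
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    # lexsort: primary key distance, tie-break by column index (lower first)
    idx = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((idx, d), axis=1)
    nn = order[:, :k]
    rows = np.repeat(np.arange(n), k)
    cols = nn.ravel()
    A = sp.csr_matrix((np.ones(n * k), (rows, cols)), shape=(n, n))
    A = A.maximum(A.T)  # union symmetrization
    A.data[:] = 1.0
    return A


def spectral_clusters(knn_adjacency, n_clusters: int, seed=0) -> ClusterAssignment:
    """Normalized-Laplacian spectral clustering with seeded k-means.

    Eigenvectors of the symmetric normalized Laplacian L = I - D^{-1/2} A
    D^{-1/2} for the ``n_clusters`` smallest eigenvalues are row-normalized
    and clustered with k-means.
    """
    from sklearn.cluster import KMeans

    A = sp.csr_matrix(knn_adjacency, dtype=float)
    n = A.shape[0]
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_clusters > n:
        raise ValueError("n_clusters exceeds the number of nodes")
    if n_clusters == 1:
        labels = np.zeros(n, dtype=int)
        return ClusterAssignment(labels, A, k=0, n_clusters=1)
    deg = np.asarray(A.sum(axis=1)).ravel()
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.maximum(deg, 1e-300)), 0.0)
    D = sp.diags(inv_sqrt)
    L = sp.identity(n) - D @ A @ D
    if n <= 200:
        vals, vecs = np.linalg.eigh(L.toarray())
        emb = vecs[:, :n_clusters]
    else:
        vals, emb = sp.linalg.eigsh(L, k=n_clusters, sigma=-1e-6, which="LM")
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=n_clusters, n_init=10, random_state=int(seed) % (2 ** 31))
    labels = km.fit_predict(emb)
    return ClusterAssignment(labels.astype(int), A, k=0, n_clusters=n_clusters)


def composition_targets(assignment: ClusterAssignment, cell_types,
                        type_order=None) -> list:
    """Per-cluster targets: type frequencies pooled over neighboring clusters.

    Two clusters neighbor each other when at least one kNN edge links their
    members; a cluster's own cells are not pooled. Clusters with no
    neighbors yield an invalid target (excluded from the loss downstream).
    """
    cell_types = np.asarray(cell_types, dtype=object)
    if type_order is None:
        type_order = sorted(set(cell_types), key=str)
    type_idx = {t: i for i, t in enumerate(type_order)}
    labels = assignment.labels
    A = assignment.knn_adjacency.tocoo()
    nc = assignment.n_clusters
    neighbor = np.zeros((nc, nc), dtype=bool)
    ci, cj = labels[A.row], labels[A.col]
    neighbor[ci, cj] = True
    neighbor[cj, ci] = True
    np.fill_diagonal(neighbor, False)
    counts = np.zeros((nc, len(type_order)))
    for c in range(nc):
        mask = labels == c
        for t in cell_types[mask]:
            counts[c, type_idx[t]] += 1
    out = []
    for c in range(nc):
        pooled = counts[neighbor[c]].sum(axis=0)
        total = pooled.sum()
        if total > 0:
            out.append(CompositionTarget(c, pooled / total, True))
        else:
            out.append(CompositionTarget(c, np.zeros(len(type_order)), False))
    return out


def permute_node_labels(graph: SpatialGraph, seed=0) -> SpatialGraph:
    """Shuffle node feature rows (and metadata) within the graph.

    The adjacency is untouched, so the per-graph multiset of features is
    conserved while any association between features and graph position is
    destroyed.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(graph.n_nodes)
    return SpatialGraph(
        adjacency=graph.adjacency,
        node_features=graph.node_features[perm],
        cell_type=None if graph.cell_type is None else graph.cell_type[perm],
        immune_flag=None if graph.immune_flag is None else graph.immune_flag[perm],
        radius=graph.radius,
        sample_id=graph.sample_id,
    )


def build_correlation_graph(markers, k: int) -> sp.csr_matrix:
    """Symmetrized kNN graph in correlation-distance space of log1p markers."""
    X = np.log1p(np.asarray(markers, dtype=float))
    n = len(X)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of cells {n}")
    sd = X.std(axis=1)
    const = sd == 0
    Xc = X - X.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(Xc, axis=1)
    norm[norm == 0] = 1.0
    corr = (Xc / norm[:, None]) @ (Xc / norm[:, None]).T
    d = 1.0 - corr
    if const.any():
        warnings.warn("constant-expression cells: correlation undefined, "
                      "assigned maximal distance")
        logger.warning("%d constant-expression cells in correlation graph", const.sum())
        d[const, :] = 2.0
        d[:, const] = 2.0
    np.fill_diagonal(d, np.inf)
    idx = np.broadcast_to(np.arange(n), (n, n))
    order = np.lexsort((idx, d), axis=1)
    nn = order[:, :k]
    rows = np.repeat(np.arange(n), k)
    A = sp.csr_matrix((np.ones(n * k), (rows, nn.ravel())), shape=(n, n))
    A = A.maximum(A.T)
    A.data[:] = 1.0
    return A


def mean_degree_table(coords_list, radii) -> pd.DataFrame:
    """Mean node degree as a function of the radius, across a set of images.

    The diagnostic used to choose sensible radius values for a cohort.
    """
    rows = []
    for r in radii:
        degs = []
        for coords in coords_list:
            A = build_radius_graph(coords, r)
            if A.shape[0]:
                degs.append(np.asarray(A.sum(axis=1)).mean())
        rows.append({"radius": r, "mean_degree": float(np.mean(degs))})
    return pd.DataFrame(rows)
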