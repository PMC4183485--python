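"""The three partitioning engines: spectral, k-means on graph metrics, MCL.

All engines consume the *unweighted* adjacency view of a network and return
a total :class:`~cartonet.core.Partition` (every node assigned exactly once).

* Spectral clustering (Meila–Shi random-walk framework): embed nodes as rows
  of the matrix of the k smallest-eigenvalue eigenvectors of a graph
  Laplacian, then cluster the rows with Euclidean k-means.
* k-means on graphs: embed each node as its row of a node-to-node distance
  matrix (shortest-path hop counts or Hamming distance between adjacency
  rows) and minimise the sum of squared errors (SSE) with Lloyd iterations;
  the SSE-versus-k curve supports elbow inspection.
* MCL (Markov Cluster): simulate flow by alternating expansion (matrix
  squaring) and inflation (elementwise power + column renormalisation) of
  the column-stochastic transition matrix until convergence; clusters are
  the connected components of the limit matrix's nonzero structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .core import DistanceMatrix, Network, Partition, adjacency_matrix

__all__ = [
    "SpectralConfig",
    "KMeansConfig",
    "MCLConfig",
    "graph_laplacian",
    "spectral_partition",
    "distance_matrix",
    "lloyd_kmeans",
    "kmeans_partition",
    "sse_scan",
    "mcl_partition",
]


@dataclass
class SpectralConfig:
    k: int
    mode: str = "normalized"  # "normalized" (random-walk) | "unnormalized"
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("normalized", "unnormalized"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.k < 2:
            raise ValueError("spectral clustering requires k >= 2")


@dataclass
class KMeansConfig:
    k: int
    metric: str = "shortest_path"  # shortest_path | hamming | euclidean
    max_iter: int = 300
    restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.metric not in ("shortest_path", "hamming", "euclidean"):
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass
class MCLConfig:
    inflation: float = 2.0
    expansion: int = 2  # fixed: expansion is matrix squaring
    prune_threshold: float = 1e-10
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if self.inflation <= 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion != 2:
            raise ValueError("expansion power is fixed at 2")


def graph_laplacian(net: Network, mode: str = "unnormalized") -> np.ndarray:
    """Graph Laplacian of the unweighted adjacency matrix.

    ``unnormalized``: L = D - A.  ``normalized`` (random-walk): L = I - D^-1 A,
    with the row of any degree-0 node replaced by the identity row.
    """
    a = adjacency_matrix(net)
    d = a.sum(axis=1)
    if mode == "unnormalized":
        return np.diag(d) - a
    if mode == "normalized":
        inv = np.divide(1.0, d, out=np.zeros_like(d), where=d > 0)
        lap = np.eye(len(d)) - inv[:, None] * a
        return lap
    raise ValueError(f"unknown mode {mode!r}")


def _spectral_embedding(net: Network, k: int, mode: str) -> np.ndarray:
    """Rows = nodes, columns = eigenvectors of the k smallest eigenvalues.

    For the random-walk Laplacian the eigenproblem is solved through the
    symmetric form I - D^-1/2 A D^-1/2 (same eigenvalues; eigenvectors map
    back via D^-1/2), which keeps everything real and numerically stable.
    Sign convention: the first nonzero entry of each eigenvector is positive.
    """
    a = adjacency_matrix(net)
    d = a.sum(axis=1)
    if mode == "unnormalized":
        lap = np.diag(d) - a
        w, v = np.linalg.eigh(lap)
    else:
        inv_sqrt = np.divide(1.0, np.sqrt(d), out=np.zeros_like(d), where=d > 0)
        lap_sym = np.eye(len(d)) - (inv_sqrt[:, None] * a) * inv_sqrt[None, :]
        w, v = np.linalg.eigh(lap_sym)
        back = np.where(d > 0, inv_sqrt, 1.0)
        v = back[:, None] * v
    order = np.argsort(w, kind="stable")[:k]
    u = v[:, order]
    for col in range(u.shape[1]):
        nz = np.nonzero(np.abs(u[:, col]) > 1e-12)[0]
        if len(nz) and u[nz[0], col] < 0:
            u[:, col] = -u[:, col]
    return u


def spectral_partition(net: Network, cfg: SpectralConfig) -> Partition:
    """Spectral clustering: k-means on the rows of the eigenvector matrix U."""
    if cfg.k > net.n_nodes:
        raise ValueError(f"k={cfg.k} exceeds node count {net.n_nodes}")
    u = _spectral_embedding(net, cfg.k, cfg.mode)
    labels, _ = lloyd_kmeans(u, cfg.k, restarts=cfg.kmeans_restarts, seed=cfg.seed)
    return Partition.from_labels(net.nodes, labels)


def distance_matrix(net: Network, metric: str) -> DistanceMatrix:
    """Node-to-node distances used to embed graphs for k-means.

    ``shortest_path``: unweighted BFS hop counts; unreachable pairs get the
    finite surrogate n (strictly larger than any path length).
    ``hamming``: number of differing entries between adjacency rows, over
    all n coordinates.
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    order = net.nodes
    n = len(order)
    if metric == "shortest_path":
        d = np.full((n, n), float(n))
        np.fill_diagonal(d, 0.0)
        idx = {lab: i for i, lab in enumerate(order)}
        for src, lengths in nx.all_pairs_shortest_path_length(net.graph):
            for dst, hops in lengths.items():
                d[idx[src], idx[dst]] = float(hops)
        return DistanceMatrix(order, d)
    if metric == "hamming":
        a = adjacency_matrix(net)
        d = cdist(a, a, metric="hamming") * n
        return DistanceMatrix(order, np.round(d))
    raise ValueError(f"unknown metric {metric!r}")


def _kmeanspp_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k-means++ seeding: spread initial centroids by squared distance."""
    n = len(x)
    centers = np.empty((k, x.shape[1]))
    centers[0] = x[rng.integers(n)]
    d2 = ((x - centers[0]) ** 2).sum(axis=1)
    for c in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[c] = x[rng.integers(n)]
        else:
            centers[c] = x[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((x - centers[c]) ** 2).sum(axis=1))
    return centers


def _uniform_init(x: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    idx = rng.choice(len(x), size=k, replace=False)
    return x[idx].copy()


def _lloyd_once(x: np.ndarray, k: int, max_iter: int, rng: np.random.Generator,
                init: str = "kmeans++"):
    centers = _kmeanspp_init(x, k, rng) if init == "kmeans++" else _uniform_init(x, k, rng)
    labels = np.full(len(x), -1)
    for _ in range(max_iter):
        d2 = cdist(x, centers, metric="sqeuclidean")
        new_labels = d2.argmin(axis=1)
        # empty cluster: reseed with the point farthest from its centroid
        cost = d2[np.arange(len(x)), new_labels].copy()
        for c in range(k):
            if not (new_labels == c).any():
                far = cost.argmax()
                new_labels[far] = c
                cost[far] = -1.0
        if (new_labels == labels).all():
            break
        labels = new_labels
        for c in range(k):
            centers[c] = x[labels == c].mean(axis=0)
    # SSE against the exact centroids (means) of the final assignment
    for c in range(k):
        if (labels == c).any():
            centers[c] = x[labels == c].mean(axis=0)
    sse = ((x - centers[labels]) ** 2).sum()
    return labels, sse


def lloyd_kmeans(x: np.ndarray, k: int, max_iter: int = 300, restarts: int = 10,
                 seed: int = 0) -> tuple[np.ndarray, float]:
    """Euclidean k-means (Lloyd): best of ``restarts`` runs by SSE.

    Centroids are arithmetic means; initialisation is k-means++; an empty
    cluster is reseeded with the point currently farthest from its centroid.
    Returns (labels, SSE).
    """
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if k > len(x):
        raise ValueError(f"k={k} exceeds number of points {len(x)}")
    rng = np.random.default_rng(seed)
    best_labels, best_sse = None, np.inf
    for r in range(max(1, restarts)):
        # alternate k-means++ with uniform distinct-point seeding: the two
        # schemes reach different basins, which matters on small instances
        init = "kmeans++" if r % 2 == 0 else "uniform"
        labels, sse = _lloyd_once(x, k, max_iter, rng, init=init)
        if sse < best_sse:
            best_labels, best_sse = labels, sse
    return best_labels, float(best_sse)


def kmeans_partition(net_or_points, cfg: KMeansConfig) -> tuple[Partition, float]:
    """k-means partition of a network (via a graph metric) or of raw points.

    For a :class:`Network`, node i is embedded as row i of the chosen
    distance matrix and clustered with Euclidean SSE k-means.  For a raw
    point array (metric="euclidean"), points are clustered directly and
    labelled by index.
    """
    if isinstance(net_or_points, Network):
        net = net_or_points
        if cfg.metric == "euclidean":
            x = adjacency_matrix(net)
        else:
            x = distance_matrix(net, cfg.metric).d
        node_labels = net.nodes
    else:
        x = np.asarray(net_or_points, dtype=float)
        if x.ndim == 1:
            x = x[:, None]
        node_labels = [str(i) for i in range(len(x))]
    labels, sse = lloyd_kmeans(x, cfg.k, max_iter=cfg.max_iter,
                               restarts=cfg.restarts, seed=cfg.seed)
    return Partition.from_labels(node_labels, labels), sse


def sse_scan(net: Network, metric: str, k_min: int, k_max: int, seed: int = 0,
             restarts: int = 10) -> list[tuple[int, float]]:
    """SSE(k) for k in [k_min, k_max]; the user picks the elbow by eye.

    No automatic elbow selection is performed — the curve is the product.
    """
    if not 1 <= k_min <= k_max <= net.n_nodes:
        raise ValueError("require 1 <= k_min <= k_max <= n")
    x = distance_matrix(net, metric).d
    curve = []
    for k in range(k_min, k_max + 1):
        _, sse = lloyd_kmeans(x, k, restarts=restarts, seed=seed + k)
        curve.append((k, sse))
    return curve


def _mcl_matrix(net: Network, cfg: MCLConfig) -> tuple[np.ndarray, bool, int]:
    """Run the MCL iteration; returns (limit matrix, converged, iterations)."""
    a = adjacency_matrix(net) + np.eye(net.n_nodes)  # self-loops stabilise the flow
    m = a / a.sum(axis=0, keepdims=True)
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        prev = m
        m = m @ m  # expansion (power 2)
        m = np.power(m, cfg.inflation)  # inflation
        m[m < cfg.prune_threshold] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        dead = colsum[0] == 0
        if dead.any():  # fully pruned column: park the node on itself
            m[dead, dead] = 1.0
            colsum = m.sum(axis=0, keepdims=True)
        m = m / colsum
        if np.abs(m - prev).max() < cfg.tol:
            converged = True
            break
    return m, converged, it


def mcl_partition(net: Network, cfg: MCLConfig | None = None) -> Partition:
    """Markov Cluster partition of a network.

    Clusters are the connected components of the nonzero structure of the
    converged matrix.  If the iteration has not converged at max_iter the
    current partition is returned and a warning is issued.
    """
    cfg = cfg or MCLConfig()
    if net.n_nodes == 0:
        raise ValueError("empty network")
    m, converged, it = _mcl_matrix(net, cfg)
    if not converged:
        warnings.warn(f"MCL did not converge within {cfg.max_iter} iterations; "
                      "returning the current partition")
    structure = nx.from_numpy_array((m + m.T) > 0)
    comp_label = {}
    for ci, comp in enumerate(nx.connected_components(structure)):
        for i in comp:
            comp_label[i] = ci
    nodes = net.nodes
    return Partition({nodes[i]: str(comp_label[i]) for i in range(len(nodes))})
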