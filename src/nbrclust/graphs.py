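"""kNN proximity-graph construction at minimal connectivity.

Point data is turned into a simple undirected graph whose nodes are sample
row indices and whose edges connect k-nearest neighbors under Euclidean
distance on the normalized feature space (edge weight = distance). The
neighbor relation is directed; an edge {u, v} exists when v is among the k
nearest of u OR u among the k nearest of v (union symmetrization; mutual-AND
is available as an option). "min-conn" is the smallest k at which this graph
is connected; because edge sets are nested in k, connectivity is monotone and
binary search applies. Experiments use min-conn plus small offsets.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform

from .preprocess import FeatureTable

__all__ = [
    "pairwise_distances",
    "knn_graph",
    "min_connectivity",
    "base_graph_grid",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]


def _as_matrix(table: FeatureTable | np.ndarray) -> np.ndarray:
    if isinstance(table, FeatureTable):
        if not table.is_complete():
            raise ValueError("graph construction requires a complete table")
        return table.values
    return np.asarray(table, dtype=float)


def pairwise_distances(table: FeatureTable | np.ndarray) -> np.ndarray:
    """Symmetric Euclidean distance matrix with zero diagonal."""
    X = _as_matrix(table)
    return squareform(pdist(X, metric="euclidean"))


def _neighbor_order(dist: np.ndarray) -> np.ndarray:
    """Row i = other nodes sorted by (distance to i, node index)."""
    n = dist.shape[0]
    d = dist.copy()
    np.fill_diagonal(d, np.inf)
    return np.argsort(d, axis=1, kind="stable")[:, : n - 1]


def _knn_edges(order: np.ndarray, dist: np.ndarray, k: int, mode: str) -> set[tuple[int, int]]:
    n = order.shape[0]
    directed: set[tuple[int, int]] = set()
    for u in range(n):
        for v in order[u, :k]:
            directed.add((u, int(v)))
    if mode == "union":
        return {(min(u, v), max(u, v)) for u, v in directed}
    if mode == "mutual":
        return {(min(u, v), max(u, v)) for u, v in directed if (v, u) in directed}
    raise ValueError(f"unknown knn mode {mode!r}")


def knn_graph(
    table: FeatureTable | np.ndarray,
    k: int,
    mode: str = "union",
    provenance: str = "full",
) -> nx.Graph:
    """Symmetrized k-nearest-neighbor graph with distance edge weights.

    Distance ties are broken by node index so builds are reproducible.
    Duplicate points are allowed and produce zero-weight edges.
    """
    dist = pairwise_distances(table)
    n = dist.shape[0]
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}], got {k}")
    order = _neighbor_order(dist)
    G = nx.Graph(knn_k=k, knn_mode=mode, provenance=provenance)
    G.add_nodes_from(range(n))
    for u, v in _knn_edges(order, dist, k, mode):
        G.add_edge(u, v, weight=float(dist[u, v]))
    return G


def _connected_at_k(order: np.ndarray, k: int, mode: str) -> bool:
    """Union-find connectivity of the kNN graph without materializing networkx."""
    n = order.shape[0]
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    if mode == "mutual":
        directed = {(u, int(v)) for u in range(n) for v in order[u, :k]}
        edges: Iterable[tuple[int, int]] = (
            (u, v) for u, v in directed if (v, u) in directed
        )
    else:
        edges = ((u, int(v)) for u in range(n) for v in order[u, :k])
    n_comp = n
    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
            n_comp -= 1
            if n_comp == 1:
                return True
    return n_comp == 1


def min_connectivity(table: FeatureTable | np.ndarray, mode: str = "union") -> int:
    """Smallest k at which the symmetrized kNN graph is connected."""
    dist = pairwise_distances(table)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("need at least two points")
    order = _neighbor_order(dist)
    lo, hi = 1, n - 1
    while lo < hi:
        mid = (lo + hi) // 2
        if _connected_at_k(order, mid, mode):
            hi = mid
        else:
            lo = mid + 1
    return lo


def base_graph_grid(
    feature_sets: dict[str, FeatureTable],
    offsets: Sequence[int] = (0, 1, 2),
    mode: str = "union",
) -> list[nx.Graph]:
    """Build one kNN graph per (feature set, connectivity offset) pair.

    Each graph is built at k = min-conn + offset for its feature set and
    tagged ``{feature_set}:minconn+{offset}`` in ``G.graph['tag']``.
    """
    if any(o < 0 for o in offsets):
        raise ValueError("offsets must be non-negative")
    graphs: list[nx.Graph] = []
    for name, table in feature_sets.items():
        k0 = min_connectivity(table, mode=mode)
        for o in offsets:
            G = knn_graph(table, k0 + o, mode=mode, provenance=name)
            G.graph["offset"] = int(o)
            G.graph["min_conn"] = int(k0)
            G.graph["tag"] = f"{name}:minconn+{o}"
            graphs.append(G)
    return graphs


def write_edgelist(G: nx.Graph, path: str | Path) -> None:
    """Tab-separated weighted edge list: node_u, node_v, weight."""
    with open(path, "w") as fh:
        for u, v, w in G.edges(data="weight", default=1.0):
            fh.write(f"{u}\t{v}\t{w:.17g}\n")


def read_edgelist(path: str | Path) -> nx.Graph:
    G = nx.Graph()
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            u, v, w = parts
            G.add_edge(_maybe_int(u), _maybe_int(v), weight=float(w))
    return G


def _maybe_int(token: str):
    try:
        return int(token)
    except ValueError:
        return token


def write_graphml(G: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(G, str(path))


def read_graphml(path: str | Path) -> nx.Graph:
    G = nx.read_graphml(str(path), node_type=str)
    return nx.relabel_nodes(G, {n: _maybe_int(n) for n in G.nodes})
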