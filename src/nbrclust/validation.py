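"""Internal cluster validation and configuration selection.

Nine label-free internal cluster validation indices (ICVIs) balancing
compactness against separation score every candidate clustering: Silhouette
(SI), Calinski-Harabasz (CH), Davies-Bouldin (DB), Dunn, Xie-Beni (XB), SD,
S_Dbw, the I index, and the nearest-neighbor-based CVNN. Two graph-quality
gates restrict admissibility: Newman modularity of the partition (>= 0.6 by
default) and a per-cluster conductance measured as the fraction of ALL graph
edges leaving the cluster (<= 0.07 by default). Configurations whose smallest
cluster falls below a size floor are discarded outright. The surviving
configuration winning the majority of the nine index votes is selected.

Notation: C_i the i-th cluster with n_i members and center c_i (mean vector),
c the grand center, d(.,.) Euclidean distance, sigma(C_i) the per-dimension
population variance vector of C_i.

Several indices deliberately follow less-common printed conventions rather
than textbook/sklearn variants: SI here is macro-averaged over clusters (each
cluster's mean silhouette weighs equally), and CVNN's compactness term sums
over clusters without dividing by k.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist, pdist, squareform

from .cluster import Clustering
from .preprocess import FeatureTable

logger = logging.getLogger(__name__)

__all__ = [
    "IndexParams",
    "FamilyNormalizers",
    "ValidationReport",
    "silhouette_index",
    "calinski_harabasz_index",
    "davies_bouldin_index",
    "dunn_index",
    "xie_beni_index",
    "geometric_validity_suite",
    "modularity",
    "conductance",
    "evaluate_clustering",
    "select_optimal",
]

INDEX_DIRECTIONS = {
    "SI": "max",
    "CH": "max",
    "DB": "min",
    "Dunn": "max",
    "XB": "min",
    "SD": "min",
    "S_Dbw": "min",
    "I": "max",
    "CVNN": "min",
}


@dataclass(frozen=True)
class IndexParams:
    """Tunables for the parametric indices.

    ``cvnn_nn``: neighbor count for CVNN's separation term. ``i_exponent``:
    exponent p of the I index. ``k_max``: largest cluster count in the family
    of configurations being compared (fixes SD's Dis(k_max) normalizer).
    """

    cvnn_nn: int = 10
    i_exponent: int = 2
    k_max: int = 5

    def __post_init__(self) -> None:
        if self.cvnn_nn < 1 or self.k_max < 1 or self.i_exponent < 1:
            raise ValueError("IndexParams fields must be positive")


@dataclass(frozen=True)
class FamilyNormalizers:
    """Cross-configuration normalizers for SD and CVNN.

    SD adds Dis(k_max), the center-dispersion term of the largest-k member of
    the compared family, scaled by Scat(k); CVNN rescales its separation and
    compactness terms by the family-wide maxima. When a configuration is
    scored alone all three default to its own values.
    """

    dis_kmax: float | None = None
    max_sep: float | None = None
    max_com: float | None = None


@dataclass
class ValidationReport:
    """All quality scores for one clustering configuration."""

    indices: dict[str, float]
    raw_terms: dict[str, float]
    modularity: float
    conductance: float
    conductance_per_cluster: dict[int, float]
    conductance_mean: float
    k: int
    mode: str
    min_cluster_size: int
    n_scored: int
    tag: str = ""
    admissible: bool = False
    votes_won: int = 0


def _points_and_labels(
    points: FeatureTable | np.ndarray, clustering: Clustering
) -> tuple[np.ndarray, np.ndarray]:
    """Rows of the scored (labelled) nodes and their integer labels.

    Nodes are sample row indices; unassigned attack nodes are excluded.
    """
    X = points.values if isinstance(points, FeatureTable) else np.asarray(points, float)
    nodes = sorted(clustering.labels)
    y = np.array([clustering.labels[v] for v in nodes], dtype=int)
    return X[np.asarray(nodes, dtype=int)], y


def _groups(y: np.ndarray) -> list[np.ndarray]:
    return [np.flatnonzero(y == c) for c in range(y.max() + 1)]


def _centers(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.vstack([X[idx].mean(axis=0) for idx in _groups(y)])


def silhouette_index(
    points: FeatureTable | np.ndarray, clustering: Clustering
) -> float:
    """Macro-averaged silhouette: mean over clusters of the cluster-mean s(x).

    a(x) is the mean distance to the other members of x's cluster, b(x) the
    smallest mean distance to another cluster. Singletons (and coincident
    degenerate points with max(a, b) = 0) contribute s(x) = 0.
    """
    X, y = _points_and_labels(points, clustering)
    k = y.max() + 1
    if k < 2:
        raise ValueError("silhouette requires at least two clusters")
    D = squareform(pdist(X))
    groups = _groups(y)
    per_cluster = []
    for gi, idx in enumerate(groups):
        svals = []
        for x in idx:
            if len(idx) == 1:
                svals.append(0.0)
                continue
            a = D[x, idx].sum() / (len(idx) - 1)
            b = min(D[x, other].mean() for gj, other in enumerate(groups) if gj != gi)
            m = max(a, b)
            svals.append((b - a) / m if m > 0 else 0.0)
        per_cluster.append(float(np.mean(svals)))
    return float(np.mean(per_cluster))


def calinski_harabasz_index(
    points: FeatureTable | np.ndarray, clustering: Clustering
) -> float:
    """Between/within dispersion ratio; +inf when within-dispersion is zero."""
    X, y = _points_and_labels(points, clustering)
    k = y.max() + 1
    n = len(y)
    if not (2 <= k < n):
        raise ValueError("CH requires 2 <= k < N")
    centers = _centers(X, y)
    grand = X.mean(axis=0)
    between = sum(
        len(idx) * float(np.sum((centers[c] - grand) ** 2))
        for c, idx in enumerate(_groups(y))
    )
    within = sum(
        float(np.sum((X[idx] - centers[c]) ** 2)) for c, idx in enumerate(_groups(y))
    )
    if within == 0:
        logger.warning("zero within-cluster dispersion; CH = +inf")
        return math.inf
    return (between / (k - 1)) / (within / (n - k))


def davies_bouldin_index(
    points: FeatureTable | np.ndarray, clustering: Clustering
) -> float:
    """Mean over clusters of the worst (S_i + S_j) / d(c_i, c_j) similarity."""
    X, y = _points_and_labels(points, clustering)
    k = y.max() + 1
    if k < 2:
        raise ValueError("DB requires at least two clusters")
    centers = _centers(X, y)
    cd = squareform(pdist(centers))
    if np.any(cd[np.triu_indices(k, 1)] == 0):
        raise ValueError("coincident cluster centers")
    S = np.array(
        [
            float(np.linalg.norm(X[idx] - centers[c], axis=1).mean())
            for c, idx in enumerate(_groups(y))
        ]
    )
    total = 0.0
    for i in range(k):
        total += max((S[i] + S[j]) / cd[i, j] for j in range(k) if j != i)
    return total / k


def dunn_index(points: FeatureTable | np.ndarray, clustering: Clustering) -> float:
    """Minimum inter-cluster point distance over maximum intra-cluster diameter."""
    X, y = _points_and_labels(points, clustering)
    k = y.max() + 1
    if k < 2:
        raise ValueError("Dunn requires at least two clusters")
    groups = _groups(y)
    max_diam = max(
        (float(pdist(X[idx]).max()) if len(idx) > 1 else 0.0) for idx in groups
    )
    if max_diam == 0:
        raise ValueError("all clusters are singletons or coincident (zero diameter)")
    min_inter = min(
        float(cdist(X[gi], X[gj]).min())
        for i, gi in enumerate(groups)
        for gj in groups[i + 1 :]
    )
    return min_inter / max_diam


def xie_beni_index(points: FeatureTable | np.ndarray, clustering: Clustering) -> float:
    """Total squared within-center scatter over N times the minimal squared center gap."""
    X, y = _points_and_labels(points, clustering)
    k = y.max() + 1
    if k < 2:
        raise ValueError("XB requires at least two clusters")
    centers = _centers(X, y)
    cd2 = squareform(pdist(centers)) ** 2
    off = cd2[np.triu_indices(k, 1)]
    if np.any(off == 0):
        raise ValueError("coincident cluster centers")
    within = sum(
        float(np.sum((X[idx] - centers[c]) ** 2)) for c, idx in enumerate(_groups(y))
    )
    return within / (len(y) * float(off.min()))


def _scat(X: np.ndarray, y: np.ndarray) -> float:
    """Average cluster variance-vector norm relative to the data's: Scat(k)."""
    groups = _groups(y)
    sigma_d = float(np.linalg.norm(X.var(axis=0)))
    if sigma_d == 0:
        raise ValueError("degenerate data: zero total variance")
    return float(
        np.mean([np.linalg.norm(X[idx].var(axis=0)) for idx in groups]) / sigma_d
    )


def _dis(centers: np.ndarray) -> float:
    """Center-dispersion term Dis(k) of the SD index."""
    k = centers.shape[0]
    cd = squareform(pdist(centers))
    off = cd[np.triu_indices(k, 1)]
    if np.any(off == 0):
        raise ValueError("coincident cluster centers in Dis term")
    total = sum(1.0 / cd[i].sum() for i in range(k))
    return float(off.max() / off.min()) * total


def _dens_bw(X: np.ndarray, y: np.ndarray, centers: np.ndarray) -> float:
    """Between-cluster density term of S_Dbw.

    A point is "within radius" of a location u when d(x, u) does not exceed
    the average cluster standard-deviation norm (1/k) sum_i ||sigma(C_i)||.
    """
    groups = _groups(y)
    k = len(groups)
    radius = float(np.mean([np.linalg.norm(X[idx].var(axis=0)) for idx in groups]))
    total = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            union = np.concatenate([groups[i], groups[j]])
            u = (centers[i] + centers[j]) / 2.0
            dens_u = int(np.sum(np.linalg.norm(X[union] - u, axis=1) <= radius))
            dens_i = int(
                np.sum(np.linalg.norm(X[groups[i]] - centers[i], axis=1) <= radius)
            )
            dens_j = int(
                np.sum(np.linalg.norm(X[groups[j]] - centers[j], axis=1) <= radius)
            )
            denom = max(dens_i, dens_j)
            total += dens_u / denom if denom > 0 else 0.0
    return total / (k * (k - 1))


def _i_index(X: np.ndarray, y: np.ndarray, centers: np.ndarray, p: int) -> float:
    groups = _groups(y)
    k = len(groups)
    grand = X.mean(axis=0)
    total_to_grand = float(np.linalg.norm(X - grand, axis=1).sum())
    within = sum(
        float(np.linalg.norm(X[idx] - centers[c], axis=1).sum())
        for c, idx in enumerate(groups)
    )
    if within == 0:
        raise ValueError("zero within-cluster scatter in I index")
    max_center = float(pdist(centers).max())
    return (total_to_grand / (k * within) * max_center) ** p


def _cvnn_terms(X: np.ndarray, y: np.ndarray, nn: int) -> tuple[float, float]:
    """Raw separation and compactness terms of CVNN (before family scaling)."""
    n = len(y)
    nn = min(nn, n - 1)
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")[:, :nn]
    groups = _groups(y)
    sep = 0.0
    for idx in groups:
        frac = [float(np.sum(y[order[x]] != y[x])) / nn for x in idx]
        sep = max(sep, float(np.mean(frac)))
    com = 0.0
    for idx in groups:
        ni = len(idx)
        if ni > 1:
            com += 2.0 / (ni * (ni - 1)) * float(pdist(X[idx]).sum())
    return sep, com


def geometric_validity_suite(
    points: FeatureTable | np.ndarray,
    clustering: Clustering,
    params: IndexParams | None = None,
    normalizers: FamilyNormalizers | None = None,
) -> dict[str, float]:
    """SD, S_Dbw, I, and CVNN, plus their raw building blocks.

    Returns a dict with the four index values and the raw terms ``Scat``,
    ``Dis``, ``Sep`` and ``Com`` so a caller comparing a family of
    configurations can recompute SD and CVNN under family-wide normalizers.
    """
    params = params or IndexParams()
    normalizers = normalizers or FamilyNormalizers()
    X, y = _points_and_labels(points, clustering)
    if y.max() + 1 < 2:
        raise ValueError("geometric indices require at least two clusters")
    centers = _centers(X, y)
    scat = _scat(X, y)
    dis = _dis(centers)
    sep, com = _cvnn_terms(X, y, params.cvnn_nn)
    dis_kmax = normalizers.dis_kmax if normalizers.dis_kmax is not None else dis
    max_sep = normalizers.max_sep if normalizers.max_sep is not None else sep
    max_com = normalizers.max_com if normalizers.max_com is not None else com
    cvnn = (sep / max_sep if max_sep > 0 else 0.0) + (
        com / max_com if max_com > 0 else 0.0
    )
    return {
        "SD": dis_kmax * scat + dis,
        "S_Dbw": scat + _dens_bw(X, y, centers),
        "I": _i_index(X, y, centers, params.i_exponent),
        "CVNN": cvnn,
        "Scat": scat,
        "Dis": dis,
        "Sep": sep,
        "Com": com,
    }


def _scored_subgraph(graph: nx.Graph, clustering: Clustering) -> nx.Graph:
    """Induced subgraph on labelled nodes; unassigned attack nodes drop out."""
    return graph.subgraph(clustering.labels.keys())


def modularity(graph: nx.Graph, clustering: Clustering) -> float:
    """Newman modularity of the partition on the labelled subgraph (unweighted)."""
    sub = _scored_subgraph(graph, clustering)
    if sub.number_of_edges() == 0:
        raise ValueError("modularity undefined on an edgeless graph")
    communities = [m for m in clustering.members() if m]
    return float(nx.algorithms.community.modularity(sub, communities, weight=None))


def conductance(
    graph: nx.Graph, clustering: Clustering
) -> tuple[float, dict[int, float], float]:
    """Per-cluster fraction of all graph edges leaving the cluster.

    Returns (max over clusters, per-cluster dict, mean over clusters). The
    maximum is the gated quantity: the worst cluster decides admissibility.
    """
    sub = _scored_subgraph(graph, clustering)
    m = sub.number_of_edges()
    if m == 0:
        raise ValueError("conductance undefined on an edgeless graph")
    per: dict[int, float] = {}
    for cid, members in enumerate(clustering.members()):
        cut = sum(1 for u in members for v in sub.neighbors(u) if v not in members)
        per[cid] = cut / m
    values = list(per.values())
    return max(values), per, float(np.mean(values))


def evaluate_clustering(
    points: FeatureTable | np.ndarray,
    graph: nx.Graph,
    clustering: Clustering,
    params: IndexParams | None = None,
    normalizers: FamilyNormalizers | None = None,
    tag: str = "",
) -> ValidationReport:
    """Score one clustering with all nine indices plus the graph-quality gates."""
    suite = geometric_validity_suite(points, clustering, params, normalizers)
    indices = {
        "SI": silhouette_index(points, clustering),
        "CH": calinski_harabasz_index(points, clustering),
        "DB": davies_bouldin_index(points, clustering),
        "Dunn": dunn_index(points, clustering),
        "XB": xie_beni_index(points, clustering),
        "SD": suite["SD"],
        "S_Dbw": suite["S_Dbw"],
        "I": suite["I"],
        "CVNN": suite["CVNN"],
    }
    cond_max, cond_per, cond_mean = conductance(graph, clustering)
    sizes = clustering.sizes()
    return ValidationReport(
        indices=indices,
        raw_terms={k: suite[k] for k in ("Scat", "Dis", "Sep", "Com")},
        modularity=modularity(graph, clustering),
        conductance=cond_max,
        conductance_per_cluster=cond_per,
        conductance_mean=cond_mean,
        k=clustering.k,
        mode=clustering.mode,
        min_cluster_size=min(sizes),
        n_scored=sum(sizes),
        tag=tag,
    )


DEFAULT_THRESHOLDS = {
    "mod": 0.6,
    "cond": 0.07,
    "size_floor_fraction": 10.0 / 2680.0,
}


def select_optimal(
    reports: Sequence[ValidationReport],
    thresholds: dict[str, float] | None = None,
) -> list[ValidationReport]:
    """Rank configurations by the nine-index majority vote under quality gates.

    Reports whose smallest cluster falls below ``size_floor_fraction * N`` are
    discarded outright. Each of the nine indices then casts one vote for the
    best surviving report in its optimal direction. The modularity and
    conductance gates act as secondary criteria rather than a pre-filter of
    the vote: ranking is by votes won, then admissibility (both gates pass),
    then silhouette, so a gate-failing report never outranks an admissible one
    with equal votes.
    """
    th = dict(DEFAULT_THRESHOLDS)
    th.update(thresholds or {})
    if not reports:
        raise ValueError("no reports to select from")
    surviving = []
    reasons = []
    for r in reports:
        floor = th["size_floor_fraction"] * r.n_scored
        if r.min_cluster_size < floor:
            reasons.append(
                f"{r.tag or r.k}: min cluster {r.min_cluster_size} < floor {floor:.1f}"
            )
            continue
        surviving.append(
            replace(
                r,
                admissible=(r.modularity >= th["mod"] and r.conductance <= th["cond"]),
                votes_won=0,
            )
        )
    if not surviving:
        raise ValueError("all configurations filtered out: " + "; ".join(reasons))
    pool = surviving
    for name, direction in INDEX_DIRECTIONS.items():
        vals = [r.indices[name] for r in pool]
        best = max(vals) if direction == "max" else min(vals)
        winner = next(r for r, v in zip(pool, vals) if v == best)
        winner.votes_won += 1
    return sorted(
        surviving,
        key=lambda r: (-r.votes_won, not r.admissible, -r.indices["SI"]),
    )
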