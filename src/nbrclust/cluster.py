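"""Node-based resilience clustering (NBR-Clust).

The pipeline: (i) point data becomes a connected proximity graph; (ii) a
greedy betweenness-centrality search finds the attack set minimizing a chosen
resilience measure; (iii) the connected components surviving the removal
become base clusters, and the attack-set nodes are either folded back into
those clusters ("reassigned" / complete clustering) or reported separately as
candidate outliers ("no_reassignment"); (iv) the clustering is adjusted to a
requested cluster count by normalized-cut merging (too many clusters) or by
recursively attacking the least-resilient cluster (too few).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .resilience import (
    ResilienceEvaluation,
    greedy_bc_minimize,
    _component_stats,
)

__all__ = [
    "Clustering",
    "components_after_removal",
    "reassign_attack_set",
    "merge_to_k",
    "split_to_k",
    "nbr_clust",
]

MODES = ("reassigned", "no_reassignment")


@dataclass
class Clustering:
    """Node-to-cluster assignment with attack-set bookkeeping.

    ``labels`` covers every graph node in reassigned mode, or V minus
    ``unassigned`` when the attack set is left out. Cluster ids are contiguous
    from 0. ``provenance`` records the measure, the graph tag, and an ordered
    adjustment trace (merges/splits/reassignments).
    """

    labels: dict
    mode: str
    unassigned: tuple = ()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "reassigned" and self.unassigned:
            raise ValueError("reassigned clustering cannot carry unassigned nodes")
        ids = sorted(set(self.labels.values()))
        if ids != list(range(len(ids))):
            raise ValueError("cluster ids must be contiguous from 0")

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def members(self) -> list[set]:
        out: list[set] = [set() for _ in range(self.k)]
        for node, c in self.labels.items():
            out[c].add(node)
        return out

    def sizes(self) -> list[int]:
        return [len(m) for m in self.members()]


def _canonical_labels(groups: Sequence[set]) -> dict:
    """Assign contiguous ids: largest group first, ties by smallest member."""
    ordered = sorted(groups, key=lambda g: (-len(g), min(g)))
    return {node: cid for cid, g in enumerate(ordered) for node in g}


def components_after_removal(
    graph: nx.Graph, s: Sequence, provenance: dict | None = None
) -> Clustering:
    """Connected components of V - S as base clusters; S left unassigned."""
    s = list(dict.fromkeys(s))  # preserve removal order, drop duplicates
    if len(s) >= graph.number_of_nodes():
        raise ValueError("attack set must be a proper subset of V")
    comps, _, _ = _component_stats(graph, s)
    return Clustering(
        labels=_canonical_labels(comps),
        mode="no_reassignment",
        unassigned=tuple(s),
        provenance=dict(provenance or {}),
    )


def reassign_attack_set(
    graph: nx.Graph, clustering: Clustering, strategy: str = "weighted"
) -> Clustering:
    """Fold attack-set nodes back into clusters by iterated neighbor voting.

    In rounds, every unassigned node adjacent to at least one labelled node
    joins the cluster winning its labelled-neighbor vote; ties go to the
    larger cluster, then the lower cluster id. Rounds repeat until the whole
    attack set is labelled. Already-labelled nodes never change.

    With ``strategy="weighted"`` (default) each labelled neighbor votes with
    weight 1/distance, so close neighbors dominate; critical attack nodes are
    precisely the high-betweenness gateways whose adjacency is rich in
    far-side edges, and an unweighted count systematically hands them to the
    wrong cluster. ``strategy="count"`` is the plain plurality over labelled
    neighbors. On unit-weight graphs the two coincide.
    """
    if clustering.mode != "no_reassignment":
        raise ValueError("clustering already has its attack set reassigned")
    if strategy not in ("weighted", "count"):
        raise ValueError("strategy must be 'weighted' or 'count'")
    labels = dict(clustering.labels)
    pending = list(clustering.unassigned)
    sizes: dict[int, int] = {}
    for c in labels.values():
        sizes[c] = sizes.get(c, 0) + 1
    while pending:
        assigned_now: list[tuple] = []
        snapshot = dict(labels)
        for node in pending:
            votes: dict[int, float] = {}
            for nb in graph.neighbors(node):
                c = snapshot.get(nb)
                if c is None:
                    continue
                if strategy == "weighted":
                    w = 1.0 / max(float(graph[node][nb].get("weight", 1.0)), 1e-12)
                else:
                    w = 1.0
                votes[c] = votes.get(c, 0.0) + w
            if not votes:
                continue
            winner = min(votes, key=lambda c: (-votes[c], -sizes[c], c))
            assigned_now.append((node, winner))
        if not assigned_now:
            raise ValueError(
                "unassigned nodes unreachable from any labelled node: "
                f"{sorted(map(str, pending))}"
            )
        for node, c in assigned_now:
            labels[node] = c
            sizes[c] += 1
        pending = [node for node in pending if node not in labels]
    prov = dict(clustering.provenance)
    prov.setdefault("adjustments", []).append(
        {"op": "reassign", "n_nodes": len(clustering.unassigned)}
    )
    return Clustering(labels=labels, mode="reassigned", unassigned=(), provenance=prov)


def _normalized_cut(graph: nx.Graph, a: set, b: set) -> float:
    cut = sum(1 for u in a for v in graph.neighbors(u) if v in b)
    return cut / (len(a) * len(b))


def merge_to_k(graph: nx.Graph, clustering: Clustering, k_target: int) -> Clustering:
    """Merge cluster pairs of maximal normalized cut E(C1,C2)/(|C1||C2|) down to k_target.

    Inter-cluster edge counts use the full graph, so components separated by
    the attack set still attract each other through it. Ties go to the
    lexicographically smallest cluster-id pair.
    """
    if not (1 <= k_target <= clustering.k):
        raise ValueError("k_target must be between 1 and the current cluster count")
    groups = {cid: g for cid, g in enumerate(clustering.members())}
    trace: list[dict] = []
    while len(groups) > k_target:
        ids = sorted(groups)
        best = None
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                score = _normalized_cut(graph, groups[a], groups[b])
                if best is None or score > best[0] + 1e-15:
                    best = (score, a, b)
        _, a, b = best
        groups[a] = groups[a] | groups[b]
        del groups[b]
        trace.append({"op": "merge", "pair": [a, b], "score": best[0]})
    prov = dict(clustering.provenance)
    prov.setdefault("adjustments", []).extend(trace)
    return Clustering(
        labels=_canonical_labels(list(groups.values())),
        mode=clustering.mode,
        unassigned=clustering.unassigned,
        provenance=prov,
    )


def split_to_k(
    graph: nx.Graph,
    clustering: Clustering,
    k_target: int,
    measure: str,
    budget: int | None = None,
    strategy: str = "weighted",
    cache: dict | None = None,
) -> Clustering:
    """Raise the cluster count by recursively attacking the least-resilient cluster.

    Among clusters of size >= 3, the one whose induced subgraph has the lowest
    greedy resilience value is re-attacked; its surviving components (with the
    inner attack set reassigned) replace it. Splits repeat until ``k_target``
    is reached; an overshoot (a split yielding more clusters than needed) is
    walked back by normalized-cut merging. ``cache`` memoizes greedy
    sub-evaluations by (measure, member set) so sweeps over k share work.
    """
    if k_target < clustering.k:
        raise ValueError("k_target below current cluster count; use merge_to_k")
    if cache is None:
        cache = {}
    groups = clustering.members()
    trace: list[dict] = []
    while len(groups) < k_target:
        # score every splittable cluster by the greedy resilience of its subgraph
        candidates: list[tuple[float, int, object]] = []
        for idx, g in enumerate(groups):
            if len(g) < 3:
                continue
            key = (measure, frozenset(g))
            if key not in cache:
                sub = graph.subgraph(g)
                if not nx.is_connected(sub):
                    cache[key] = "disconnected"  # free split into its components
                else:
                    ev = greedy_bc_minimize(sub, measure, budget=budget)
                    cache[key] = ev if ev.n_components >= 2 else "unsplittable"
            val = cache[key]
            if val == "unsplittable":
                continue
            score = float("-inf") if val == "disconnected" else val.objective
            candidates.append((score, idx, val))
        if not candidates:
            raise ValueError(
                f"no splittable cluster remains; achievable k = {len(groups)}"
            )
        candidates.sort(key=lambda t: (t[0], t[1]))
        _, idx, ev = candidates[0]
        sub = graph.subgraph(groups[idx])
        if ev == "disconnected":
            parts = [set(c) for c in nx.connected_components(sub)]
        else:
            base = components_after_removal(sub, ev.attack_set)
            parts = reassign_attack_set(sub, base, strategy=strategy).members()
        trace.append({"op": "split", "cluster_size": len(groups[idx]),
                      "n_parts": len(parts)})
        groups = [g for i, g in enumerate(groups) if i != idx] + parts
    prov = dict(clustering.provenance)
    prov.setdefault("adjustments", []).extend(trace)
    result = Clustering(
        labels=_canonical_labels(groups),
        mode=clustering.mode,
        unassigned=clustering.unassigned,
        provenance=prov,
    )
    if result.k > k_target:
        result = merge_to_k(graph, result, k_target)
    return result


def nbr_clust(
    graph: nx.Graph,
    measure: str,
    k_target: int,
    mode: str = "reassigned",
    budget: int | None = None,
    evaluation: ResilienceEvaluation | None = None,
    strategy: str = "weighted",
    split_cache: dict | None = None,
) -> Clustering:
    """Full resilience-clustering pipeline on a connected graph.

    ``evaluation`` may carry a precomputed greedy attack for this graph and
    measure (useful when sweeping k over the same graph); otherwise the greedy
    search runs here. ``strategy`` selects the attack-set reassignment vote
    (see :func:`reassign_attack_set`).

    Both modes share one clustering of V: the attack set is folded back in
    before the merge/split adjustment (surviving components are frequently
    linked only *through* the removed attack core, so bare components carry no
    inter-cluster edges and the normalized-cut merge would be blind), and
    ``no_reassignment`` output is that clustering restricted to V - S. The two
    modes therefore agree exactly on the surviving nodes.
    """
    if k_target < 2:
        raise ValueError("k_target must be at least 2")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    if evaluation is None:
        evaluation = greedy_bc_minimize(graph, measure, budget=budget)
    elif evaluation.measure != measure:
        raise ValueError("precomputed evaluation is for a different measure")
    prov = {
        "measure": measure,
        "graph": graph.graph.get("tag", ""),
        "objective": evaluation.objective,
        "attack_set_size": len(evaluation.attack_set),
        "mode": mode,
    }
    base = components_after_removal(graph, evaluation.attack_set, provenance=prov)
    clustering = reassign_attack_set(graph, base, strategy=strategy)
    if clustering.k > k_target:
        clustering = merge_to_k(graph, clustering, k_target)
    elif clustering.k < k_target:
        clustering = split_to_k(
            graph,
            clustering,
            k_target,
            measure,
            budget=budget,
            strategy=strategy,
            cache=split_cache,
        )
    if mode == "no_reassignment":
        attack = set(evaluation.attack_set)
        groups = [g - attack for g in clustering.members()]
        groups = [g for g in groups if g]
        clustering = Clustering(
            labels=_canonical_labels(groups),
            mode="no_reassignment",
            unassigned=tuple(evaluation.attack_set),
            provenance=clustering.provenance,
        )
    return clustering
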