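"""Node-based resilience measures and critical-attack-set search.

A node-based resilience measure scores how badly the removal of an attack set
S of vertices fragments a connected graph G = (V, E). Three measures are
implemented, each as an objective over S whose minimum defines the graph's
resilience:

* vertex attack tolerance (VAT):  |S| / (|V - S - C_max(V-S)| + 1)
* normalized integrity:           (|S| + C_max(V-S)) / |V|
* tenacity:                       (|S| + C_max(V-S)) / omega(V-S)

where C_max is the size of the largest connected component surviving the
removal and omega counts surviving components. Small values mean a cheap
attack shatters the graph, and the minimizing S plays the role of the
"boundary" between natural clusters.

Minimizing over all subsets is exponential; the Greedy-BC heuristic instead
removes the node of highest weighted betweenness centrality, recomputes
centralities, removes the next highest, and so on; every removal prefix
S_1 subset S_2 subset ... is scored and the best prefix returned. Exhaustive
enumeration is provided as an oracle for small graphs. Edge weights are
distances (smaller = closer) and act as shortest-path lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations
from typing import Iterable, Sequence

import igraph as ig
import networkx as nx

__all__ = [
    "MEASURES",
    "ResilienceEvaluation",
    "vat_objective",
    "integrity_objective",
    "tenacity_objective",
    "resilience_objective",
    "weighted_betweenness",
    "greedy_bc_minimize",
    "exact_resilience",
]

MEASURES = ("vat", "integrity", "tenacity")

# weights passed to shortest-path routines must be strictly positive;
# duplicate points yield zero-length edges, floored here
_MIN_WEIGHT = 1e-12


@dataclass(frozen=True)
class ResilienceEvaluation:
    """Outcome of evaluating (or minimizing) a resilience measure.

    ``attack_set`` preserves removal order. ``components`` partitions the
    surviving vertices V - S. ``trace`` holds ``(|S|, objective)`` for every
    candidate prefix examined by the greedy search (empty for single-set
    evaluations).
    """

    measure: str
    attack_set: tuple
    objective: float
    cmax: int
    n_components: int
    components: tuple[frozenset, ...]
    trace: tuple[tuple[int, float], ...] = field(default=())


def _check_measure(measure: str) -> None:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")


def _component_stats(graph: nx.Graph, s: Iterable) -> tuple[list[set], int, int]:
    s = set(s)
    remaining = [v for v in graph.nodes if v not in s]
    comps = [set(c) for c in nx.connected_components(graph.subgraph(remaining))]
    cmax = max((len(c) for c in comps), default=0)
    return comps, cmax, len(comps)


def _objective_from_counts(
    measure: str, n: int, s_size: int, cmax: int, omega: int
) -> float:
    if measure == "vat":
        return s_size / (n - s_size - cmax + 1)
    if measure == "integrity":
        return (s_size + cmax) / n
    return (s_size + cmax) / omega  # tenacity


def vat_objective(graph: nx.Graph, s: Sequence) -> float:
    """VAT objective |S| / (|V-S-C_max(V-S)| + 1); S must be non-empty and proper."""
    s = list(s)
    if not s:
        raise ValueError("VAT requires a non-empty attack set")
    if len(set(s)) >= graph.number_of_nodes():
        raise ValueError("attack set must be a proper subset of V")
    _, cmax, _ = _component_stats(graph, s)
    return _objective_from_counts("vat", graph.number_of_nodes(), len(set(s)), cmax, 1)


def integrity_objective(graph: nx.Graph, s: Sequence) -> float:
    """Integrity objective (|S| + C_max(V-S)) / |V|; S may be empty or all of V."""
    s = set(s)
    _, cmax, _ = _component_stats(graph, s)
    return _objective_from_counts("integrity", graph.number_of_nodes(), len(s), cmax, 1)


def tenacity_objective(graph: nx.Graph, s: Sequence) -> float:
    """Tenacity objective (|S| + C_max(V-S)) / omega(V-S); S must be proper."""
    s = set(s)
    if len(s) >= graph.number_of_nodes():
        raise ValueError("tenacity requires V - S to be non-empty")
    _, cmax, omega = _component_stats(graph, s)
    return _objective_from_counts("tenacity", graph.number_of_nodes(), len(s), cmax, omega)


def resilience_objective(graph: nx.Graph, measure: str, s: Sequence) -> float:
    _check_measure(measure)
    fn = {
        "vat": vat_objective,
        "integrity": integrity_objective,
        "tenacity": tenacity_objective,
    }[measure]
    return fn(graph, s)


def _to_igraph(graph: nx.Graph) -> tuple[ig.Graph, list]:
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in graph.edges]
    weights = [
        max(float(d.get("weight", 1.0)), _MIN_WEIGHT)
        for _, _, d in graph.edges(data=True)
    ]
    g = ig.Graph(n=len(nodes), edges=edges)
    g.es["weight"] = weights
    return g, nodes


def weighted_betweenness(graph: nx.Graph) -> dict:
    """Unnormalized weighted betweenness centrality per node.

    Edge weights are treated as path lengths; each unordered vertex pair
    contributes the fraction of its minimum-weight shortest paths passing
    through the node.
    """
    if graph.number_of_nodes() < 2:
        raise ValueError("betweenness requires at least two nodes")
    for _, _, d in graph.edges(data=True):
        if float(d.get("weight", 1.0)) < 0:
            raise ValueError("negative edge weights are not allowed")
    g, nodes = _to_igraph(graph)
    bc = g.betweenness(weights="weight" if g.ecount() else None)
    return {v: float(b) for v, b in zip(nodes, bc)}


def greedy_bc_minimize(
    graph: nx.Graph, measure: str, budget: int | None = None
) -> ResilienceEvaluation:
    """Minimize a resilience objective over greedy betweenness-removal prefixes.

    Repeatedly deletes the current highest-betweenness node (recomputing
    centralities after every deletion; ties go to the lowest node index),
    scoring the objective after each deletion. Stops after ``budget`` removals
    (default ``|V| - 2``) and returns the prefix of minimal objective, smaller
    prefixes winning ties.
    """
    _check_measure(measure)
    n = graph.number_of_nodes()
    if n < 3:
        raise ValueError("greedy search needs at least three nodes")
    if not nx.is_connected(graph):
        raise ValueError(
            "input graph is disconnected; cluster its components separately"
        )
    if budget is None:
        budget = n - 2
    budget = min(budget, n - 2)
    if budget < 1:
        raise ValueError("budget must allow at least one removal")

    g, nodes = _to_igraph(graph)
    g.vs["nid"] = nodes
    order: list = []
    trace: list[tuple[int, float]] = []
    best_obj = float("inf")
    best_size = 0
    for step in range(budget):
        weights = g.es["weight"] if g.ecount() else None
        bc = g.betweenness(weights=weights)
        top = max(bc)
        tol = 1e-9 * max(1.0, abs(top))
        candidates = [i for i, b in enumerate(bc) if b >= top - tol]
        victim = min(candidates, key=lambda i: g.vs[i]["nid"])
        order.append(g.vs[victim]["nid"])
        g.delete_vertices(victim)
        sizes = g.connected_components().sizes()
        cmax = max(sizes) if sizes else 0
        omega = len(sizes)
        obj = _objective_from_counts(measure, n, len(order), cmax, omega)
        trace.append((len(order), obj))
        if obj < best_obj:
            best_obj = obj
            best_size = len(order)

    best_set = tuple(order[:best_size])
    comps, cmax, omega = _component_stats(graph, best_set)
    obj = _objective_from_counts(measure, n, best_size, cmax, omega)
    return ResilienceEvaluation(
        measure=measure,
        attack_set=best_set,
        objective=obj,
        cmax=cmax,
        n_components=omega,
        components=tuple(frozenset(c) for c in comps),
        trace=tuple(trace),
    )


def _admissible_subsets(nodes: list, measure: str):
    n = len(nodes)
    if measure == "vat":
        sizes = range(1, n)  # non-empty proper
    elif measure == "integrity":
        sizes = range(0, n + 1)  # empty and V allowed
    else:  # tenacity: proper (possibly empty)
        sizes = range(0, n)
    return chain.from_iterable(combinations(nodes, r) for r in sizes)


def exact_resilience(
    graph: nx.Graph, measure: str, max_nodes: int = 15
) -> ResilienceEvaluation:
    """Global minimum of a resilience objective by exhaustive subset enumeration.

    Intended as an oracle on small graphs; refuses graphs beyond ``max_nodes``.
    """
    _check_measure(measure)
    n = graph.number_of_nodes()
    if n > max_nodes:
        raise ValueError(f"exact search limited to {max_nodes} nodes, got {n}")
    nodes = sorted(graph.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    adj = [[index[u] for u in graph.neighbors(v)] for v in nodes]

    best: tuple[float, int, tuple] | None = None
    for subset in _admissible_subsets(nodes, measure):
        removed = [False] * n
        for v in subset:
            removed[index[v]] = True
        # components of the surviving vertices via DFS on adjacency lists
        seen = list(removed)
        cmax = 0
        omega = 0
        for start in range(n):
            if seen[start]:
                continue
            omega += 1
            stack = [start]
            seen[start] = True
            size = 0
            while stack:
                x = stack.pop()
                size += 1
                for y in adj[x]:
                    if not seen[y]:
                        seen[y] = True
                        stack.append(y)
            cmax = max(cmax, size)
        omega_safe = max(omega, 1)  # S = V (integrity only): cmax = 0
        obj = _objective_from_counts(measure, n, len(subset), cmax, omega_safe)
        key = (obj, len(subset), subset)
        if best is None or key < best:
            best = key

    assert best is not None
    obj, _, subset = best
    comps, cmax, omega = _component_stats(graph, subset)
    return ResilienceEvaluation(
        measure=measure,
        attack_set=tuple(subset),
        objective=obj,
        cmax=cmax,
        n_components=omega,
        components=tuple(frozenset(c) for c in comps),
    )
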