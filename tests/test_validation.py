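import math

import networkx as nx
import numpy as np
import pytest

from nbrclust.cluster import Clustering
from nbrclust.synthetic import toy_graph
from nbrclust.validation import (
    FamilyNormalizers,
    IndexParams,
    ValidationReport,
    calinski_harabasz_index,
    conductance,
    davies_bouldin_index,
    dunn_index,
    evaluate_clustering,
    geometric_validity_suite,
    modularity,
    select_optimal,
    silhouette_index,
    xie_beni_index,
)

# ---------------------------------------------------------------------------
# naive single-purpose re-implementations used as independent oracles
# ---------------------------------------------------------------------------


def d(x, y):
    return float(np.linalg.norm(np.asarray(x) - np.asarray(y)))


def clusters_of(y):
    return [[i for i, c in enumerate(y) if c == k] for k in sorted(set(y))]


def naive_silhouette(X, y):
    per_cluster = []
    for ci in clusters_of(y):
        vals = []
        for x in ci:
            if len(ci) == 1:
                vals.append(0.0)
                continue
            a = sum(d(X[x], X[o]) for o in ci if o != x) / (len(ci) - 1)
            b = min(
                sum(d(X[x], X[o]) for o in cj) / len(cj)
                for cj in clusters_of(y)
                if cj != ci
            )
            vals.append((b - a) / max(a, b) if max(a, b) > 0 else 0.0)
        per_cluster.append(sum(vals) / len(vals))
    return sum(per_cluster) / len(per_cluster)


def naive_ch(X, y):
    cs = clusters_of(y)
    k, n = len(cs), len(y)
    grand = np.mean(X, axis=0)
    centers = [np.mean(X[ci], axis=0) for ci in cs]
    between = sum(len(ci) * d(c, grand) ** 2 for ci, c in zip(cs, centers))
    within = sum(d(X[x], c) ** 2 for ci, c in zip(cs, centers) for x in ci)
    return (between / (k - 1)) / (within / (n - k))


def naive_db(X, y):
    cs = clusters_of(y)
    centers = [np.mean(X[ci], axis=0) for ci in cs]
    S = [
        sum(d(X[x], c) for x in ci) / len(ci) for ci, c in zip(cs, centers)
    ]
    total = 0.0
    for i in range(len(cs)):
        total += max(
            (S[i] + S[j]) / d(centers[i], centers[j])
            for j in range(len(cs))
            if j != i
        )
    return total / len(cs)


def naive_dunn(X, y):
    cs = clusters_of(y)
    diam = max(
        (max((d(X[a], X[b]) for a in ci for b in ci), default=0.0) for ci in cs)
    )
    inter = min(
        d(X[a], X[b])
        for i, ci in enumerate(cs)
        for cj in cs[i + 1 :]
        for a in ci
        for b in cj
    )
    return inter / diam


def naive_xb(X, y):
    cs = clusters_of(y)
    centers = [np.mean(X[ci], axis=0) for ci in cs]
    within = sum(d(X[x], c) ** 2 for ci, c in zip(cs, centers) for x in ci)
    min_cd = min(
        d(centers[i], centers[j]) ** 2
        for i in range(len(cs))
        for j in range(len(cs))
        if i != j
    )
    return within / (len(y) * min_cd)


def naive_scat(X, y):
    cs = clusters_of(y)
    sig_d = np.linalg.norm(np.var(X, axis=0))
    return sum(np.linalg.norm(np.var(X[ci], axis=0)) for ci in cs) / (len(cs) * sig_d)


def naive_dis(X, y):
    cs = clusters_of(y)
    centers = [np.mean(X[ci], axis=0) for ci in cs]
    k = len(cs)
    cds = [d(centers[i], centers[j]) for i in range(k) for j in range(k) if i < j]
    total = sum(
        1.0 / sum(d(centers[i], centers[j]) for j in range(k)) for i in range(k)
    )
    return max(cds) / min(cds) * total


def naive_s_dbw(X, y):
    cs = clusters_of(y)
    k = len(cs)
    centers = [np.mean(X[ci], axis=0) for ci in cs]
    radius = sum(np.linalg.norm(np.var(X[ci], axis=0)) for ci in cs) / k

    def f(points, u):
        return sum(1 for p in points if d(X[p], u) <= radius)

    dens = 0.0
    for i in range(k):
        for j in range(k):
            if i == j:
                continue
            u = (centers[i] + centers[j]) / 2
            denom = max(f(cs[i], centers[i]), f(cs[j], centers[j]))
            dens += (f(cs[i] + cs[j], u) / denom) if denom else 0.0
    return naive_scat(X, y) + dens / (k * (k - 1))


def naive_i_index(X, y, p=2):
    cs = clusters_of(y)
    k = len(cs)
    grand = np.mean(X, axis=0)
    centers = [np.mean(X[ci], axis=0) for ci in cs]
    num = sum(d(X[x], grand) for x in range(len(y)))
    within = sum(d(X[x], c) for ci, c in zip(cs, centers) for x in ci)
    max_cd = max(
        d(centers[i], centers[j]) for i in range(k) for j in range(k) if i != j
    )
    return (num / (k * within) * max_cd) ** p


def naive_cvnn_terms(X, y, nn):
    n = len(y)
    sep = 0.0
    for ci in clusters_of(y):
        fr = []
        for x in ci:
            order = sorted((o for o in range(n) if o != x), key=lambda o: (d(X[x], X[o]), o))
            q = sum(1 for o in order[:nn] if y[o] != y[x])
            fr.append(q / nn)
        sep = max(sep, sum(fr) / len(fr))
    com = 0.0
    for ci in clusters_of(y):
        ni = len(ci)
        if ni > 1:
            com += (
                2.0
                / (ni * (ni - 1))
                * sum(d(X[a], X[b]) for i, a in enumerate(ci) for b in ci[i + 1 :])
            )
    return sep, com


def as_clustering(y):
    return Clustering(labels={i: int(c) for i, c in enumerate(y)}, mode="reassigned")


# ---------------------------------------------------------------------------


WIDE = np.array([[0.0, 0.0], [0.0, 2.0], [10.0, 0.0], [10.0, 2.0]])
NARROW = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 0.0], [10.0, 1.0]])
PAIR_LABELS = [0, 0, 1, 1]


class TestHandValues:
    def test_silhouette(self):
        got = silhouette_index(NARROW, as_clustering(PAIR_LABELS))
        a, b = 1.0, (10 + math.sqrt(101)) / 2
        assert got == pytest.approx((b - a) / b, abs=1e-9)
        assert got == pytest.approx(0.9003, abs=1e-4)

    def test_calinski_harabasz(self):
        assert calinski_harabasz_index(WIDE, as_clustering(PAIR_LABELS)) == (
            pytest.approx(50.0, abs=1e-9)
        )

    def test_davies_bouldin(self):
        assert davies_bouldin_index(WIDE, as_clustering(PAIR_LABELS)) == (
            pytest.approx(0.2, abs=1e-9)
        )

    def test_dunn(self):
        assert dunn_index(NARROW, as_clustering(PAIR_LABELS)) == pytest.approx(10.0)

    def test_xie_beni(self):
        assert xie_beni_index(WIDE, as_clustering(PAIR_LABELS)) == (
            pytest.approx(0.01, abs=1e-12)
        )

    def test_scat_i_and_cvnn_terms(self):
        suite = geometric_validity_suite(
            WIDE, as_clustering(PAIR_LABELS), IndexParams(cvnn_nn=1)
        )
        assert suite["Scat"] == pytest.approx(1 / math.sqrt(626), abs=1e-12)
        assert suite["Scat"] == pytest.approx(0.04, abs=1e-3)
        assert suite["I"] == pytest.approx(650.0, abs=1e-9)
        assert suite["Sep"] == 0.0


class TestDegenerateConventions:
    def test_coincident_cluster_pairs_have_unit_silhouette(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        assert silhouette_index(X, as_clustering(PAIR_LABELS)) == 1.0

    def test_fully_coincident_data_scores_zero(self):
        X = np.zeros((4, 2))
        assert silhouette_index(X, as_clustering(PAIR_LABELS)) == 0.0

    def test_zero_within_dispersion_gives_infinite_ch(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        assert calinski_harabasz_index(X, as_clustering(PAIR_LABELS)) == math.inf

    def test_singleton_clusters_have_zero_db(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        assert davies_bouldin_index(X, as_clustering([0, 1])) == 0.0

    def test_all_singletons_break_dunn(self):
        X = np.array([[0.0, 0.0], [5.0, 5.0]])
        with pytest.raises(ValueError, match="singleton|diameter"):
            dunn_index(X, as_clustering([0, 1]))

    def test_coincident_centers_rejected(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.raises(ValueError, match="coincident"):
            davies_bouldin_index(X, as_clustering(PAIR_LABELS))


@pytest.fixture(scope="module")
def random_sets():
    rng = np.random.default_rng(42)
    sets = []
    for _ in range(50):
        n = int(rng.integers(8, 25))
        k = int(rng.integers(2, 5))
        X = rng.random((n, 3)) + rng.integers(0, 3, (n, 1)) * 1.0
        y = rng.integers(0, k, n)
        for c in range(k):  # ensure non-singleton clusters for every index
            y[2 * c : 2 * c + 2] = c
        sets.append((X, y))
    return sets


class TestOracleAgreement:
    def test_all_nine_indices_match_direct_formula_evaluation(self, random_sets):
        params = IndexParams(cvnn_nn=3)
        for X, y in random_sets:
            c = as_clustering(y)
            assert silhouette_index(X, c) == pytest.approx(naive_silhouette(X, y), abs=1e-9)
            assert calinski_harabasz_index(X, c) == pytest.approx(naive_ch(X, y), abs=1e-9)
            assert davies_bouldin_index(X, c) == pytest.approx(naive_db(X, y), abs=1e-9)
            assert dunn_index(X, c) == pytest.approx(naive_dunn(X, y), abs=1e-9)
            assert xie_beni_index(X, c) == pytest.approx(naive_xb(X, y), abs=1e-9)
            suite = geometric_validity_suite(X, c, params)
            assert suite["Scat"] == pytest.approx(naive_scat(X, y), abs=1e-9)
            assert suite["Dis"] == pytest.approx(naive_dis(X, y), abs=1e-9)
            assert suite["SD"] == pytest.approx(
                naive_dis(X, y) * naive_scat(X, y) + naive_dis(X, y), abs=1e-9
            )
            assert suite["S_Dbw"] == pytest.approx(naive_s_dbw(X, y), abs=1e-9)
            assert suite["I"] == pytest.approx(naive_i_index(X, y), abs=1e-9)
            sep, com = naive_cvnn_terms(X, y, 3)
            assert suite["Sep"] == pytest.approx(sep, abs=1e-9)
            assert suite["Com"] == pytest.approx(com, abs=1e-9)

    def test_ch_and_db_also_match_sklearn(self, random_sets):
        from sklearn.metrics import calinski_harabasz_score, davies_bouldin_score

        for X, y in random_sets[:10]:
            c = as_clustering(y)
            assert calinski_harabasz_index(X, c) == pytest.approx(
                calinski_harabasz_score(X, y), rel=1e-9
            )
            assert davies_bouldin_index(X, c) == pytest.approx(
                davies_bouldin_score(X, y), rel=1e-9
            )

    def test_index_bounds_on_random_inputs(self, random_sets):
        for X, y in random_sets[:20]:
            c = as_clustering(y)
            assert -1.0 <= silhouette_index(X, c) <= 1.0
            assert dunn_index(X, c) >= 0.0
            assert calinski_harabasz_index(X, c) >= 0.0


class TestGraphQuality:
    def test_two_disjoint_triangles_modularity(self):
        G = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        c = Clustering(labels={0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}, mode="reassigned")
        assert modularity(G, c) == pytest.approx(0.5, abs=1e-9)

    def test_single_cluster_modularity_is_zero(self):
        G = toy_graph("cycle", 6)
        c = Clustering(labels={v: 0 for v in G.nodes}, mode="reassigned")
        assert modularity(G, c) == pytest.approx(0.0, abs=1e-12)

    def test_modularity_never_exceeds_one(self):
        rng = np.random.default_rng(5)
        G = nx.complete_graph(8)
        for _ in range(10):
            y = rng.integers(0, 3, 8)
            y[:3] = [0, 1, 2]
            c = Clustering(labels={i: int(v) for i, v in enumerate(y)}, mode="reassigned")
            assert modularity(G, c) <= 1.0

    def test_modularity_matches_newman_formula(self):
        rng = np.random.default_rng(9)
        G = nx.gnm_random_graph(12, 30, seed=3)
        y = rng.integers(0, 3, 12)
        y[:3] = [0, 1, 2]
        c = Clustering(labels={i: int(v) for i, v in enumerate(y)}, mode="reassigned")
        m = G.number_of_edges()
        q = 0.0
        for k in range(3):
            members = {i for i in range(12) if y[i] == k}
            e_c = sum(1 for u, v in G.edges if u in members and v in members)
            deg_c = sum(dv for v, dv in G.degree if v in members)
            q += e_c / m - (deg_c / (2 * m)) ** 2
        assert modularity(G, c) == pytest.approx(q, abs=1e-12)

    def test_bridged_triangles_conductance(self):
        G = toy_graph("bridge_cliques", 6)
        c = Clustering(labels={0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}, mode="reassigned")
        cmax, per, cmean = conductance(G, c)
        assert cmax == pytest.approx(1 / 7, abs=1e-9)
        assert per[0] == per[1] == pytest.approx(1 / 7)

    def test_whole_graph_and_disjoint_components_have_zero_conductance(self):
        G = toy_graph("cycle", 6)
        whole = Clustering(labels={v: 0 for v in G.nodes}, mode="reassigned")
        assert conductance(G, whole)[0] == 0.0
        H = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
        c = Clustering(labels={0: 0, 1: 0, 2: 0, 3: 1, 4: 1, 5: 1}, mode="reassigned")
        assert conductance(H, c)[0] == 0.0
        assert 0.0 <= conductance(H, c)[0] <= 1.0

    def test_unassigned_attack_nodes_excluded_from_tallies(self):
        G = toy_graph("star", 6)
        c = Clustering(
            labels={v: v - 1 for v in range(1, 6)},
            mode="no_reassignment",
            unassigned=(0,),
        )
        # without the center the leaves are isolated: edgeless graph
        with pytest.raises(ValueError, match="edgeless"):
            conductance(G, c)


def make_report(tag, si=0.5, votes_template=None, mod=0.7, cond=0.01, k=3,
                min_size=50, n=400, **overrides):
    indices = {
        "SI": si, "CH": 100.0, "DB": 1.0, "Dunn": 0.5, "XB": 0.5,
        "SD": 5.0, "S_Dbw": 1.0, "I": 0.5, "CVNN": 1.0,
    }
    indices.update(overrides)
    return ValidationReport(
        indices=indices,
        raw_terms={"Scat": 0.1, "Dis": 1.0, "Sep": 0.1, "Com": 1.0},
        modularity=mod,
        conductance=cond,
        conductance_per_cluster={},
        conductance_mean=cond,
        k=k,
        mode="reassigned",
        min_cluster_size=min_size,
        n_scored=n,
        tag=tag,
    )


class TestSelectOptimal:
    def test_single_report_collects_all_nine_votes(self):
        ranked = select_optimal([make_report("only")])
        assert ranked[0].votes_won == 9

    def test_majority_winner_ranks_first(self):
        # A best on 6 indices, B on 3
        a = make_report("A", SI=0.9, CH=200.0, DB=0.5, Dunn=1.0, XB=0.1, SD=2.0)
        b = make_report("B", S_Dbw=0.5, I=2.0, CVNN=0.5)
        ranked = select_optimal([a, b])
        assert ranked[0].tag == "A"
        assert ranked[0].votes_won == 6
        assert ranked[1].votes_won == 3

    def test_small_cluster_configurations_discarded_before_voting(self):
        good = make_report("good")
        tiny = make_report("tiny", SI=0.99, min_size=1)
        ranked = select_optimal([good, tiny])
        assert [r.tag for r in ranked] == ["good"]

    def test_gate_failure_breaks_vote_ties(self):
        # a and b tie at 4 votes each; only a passes the gates
        a = make_report("admissible", mod=0.7, cond=0.01,
                        SI=0.9, CH=200.0, DB=0.5, Dunn=1.0)
        b = make_report("gated_out", mod=0.3, cond=0.2,
                        XB=0.1, SD=2.0, S_Dbw=0.5, I=2.0)
        c = make_report("third", CVNN=0.5)
        ranked = select_optimal([a, b, c])
        assert ranked[0].votes_won == ranked[1].votes_won == 4
        assert ranked[0].tag == "admissible"
        assert ranked[0].admissible and not ranked[1].admissible

    def test_all_filtered_out_is_an_error(self):
        with pytest.raises(ValueError, match="filtered out"):
            select_optimal([make_report("tiny", min_size=0)])
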