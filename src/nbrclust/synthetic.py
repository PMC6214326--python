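"""Synthetic feature tables and toy graphs for pipeline development and testing.

The clustering framework was designed around instrument-score phenotype
tables (hundreds-to-thousands of samples, a few dozen bounded numeric
features, a sprinkle of missing values, a few highly correlated score pairs).
Real tables of that kind are typically access-restricted, so this module
generates stand-ins with the same statistical structure: isotropic
Gaussian-mixture tables with planted labels, configurable separation,
uniform-background outliers, near-duplicate feature pairs and random missing
cells; plus small named unit-weight graphs used as analytic fixtures for the
resilience measures.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import FeatureTable

__all__ = [
    "MixtureSpec",
    "gaussian_mixture_table",
    "toy_graph",
    "phenotype_like_table",
    "write_truth",
    "read_truth",
]


@dataclass(frozen=True)
class MixtureSpec:
    """Recipe for a Gaussian-mixture feature table.

    ``separation`` is the minimal between-center distance in units of the
    within-cluster standard deviation (sigma = 1). ``correlated_pairs``
    appends that many noisy copies of leading features (|r| > 0.9).
    ``outlier_fraction`` of the rows are drawn uniformly over the bounding box
    and labelled -1.
    """

    n: int = 400
    d: int = 5
    k_true: int = 4
    separation: float = 8.0
    outlier_fraction: float = 0.0
    correlated_pairs: int = 0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d < 1 or self.k_true < 1:
            raise ValueError("d and k_true must be positive")
        if self.n < 10 * self.k_true:
            raise ValueError("need at least 10 samples per planted cluster")
        if not (0.0 <= self.outlier_fraction <= 0.2):
            raise ValueError("outlier_fraction must be in [0, 0.2]")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.correlated_pairs < 0 or self.correlated_pairs > self.d:
            raise ValueError("correlated_pairs must be in [0, d]")


def _spread_centers(rng: np.random.Generator, k: int, d: int, separation: float) -> np.ndarray:
    """k centers whose minimal pairwise distance equals ``separation``."""
    if k == 1:
        return np.zeros((1, d))
    while True:
        centers = rng.standard_normal((k, d))
        dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
        min_d = dists[np.triu_indices(k, 1)].min()
        if min_d > 1e-6:
            return centers * (separation / min_d)


def gaussian_mixture_table(spec: MixtureSpec) -> tuple[FeatureTable, np.ndarray]:
    """Sample a mixture table; returns (table, planted labels; outliers = -1)."""
    rng = np.random.default_rng(spec.seed)
    n_out = int(round(spec.outlier_fraction * spec.n))
    n_in = spec.n - n_out
    centers = _spread_centers(rng, spec.k_true, spec.d, spec.separation)
    labels_in = np.sort(rng.integers(0, spec.k_true, size=n_in))
    # guarantee every planted cluster is populated
    labels_in[: spec.k_true] = np.arange(spec.k_true)
    X_in = centers[labels_in] + rng.standard_normal((n_in, spec.d))
    lo, hi = X_in.min(axis=0), X_in.max(axis=0)
    X_out = rng.uniform(lo, hi, size=(n_out, spec.d))
    X = np.vstack([X_in, X_out])
    labels = np.concatenate([labels_in, -np.ones(n_out, dtype=int)])
    perm = rng.permutation(spec.n)
    X, labels = X[perm], labels[perm]

    names = [f"f{j}" for j in range(spec.d)]
    for p in range(spec.correlated_pairs):
        dup = X[:, p] + 0.25 * rng.standard_normal(spec.n)
        X = np.column_stack([X, dup])
        names.append(f"f{p}_dup")

    mask = rng.random(X.shape) < spec.missing_fraction
    # never blank out a full column
    full_cols = mask.all(axis=0)
    mask[:, full_cols] = False

    ranges = {
        name: (float(np.floor(X[:, j].min()) - 1.0), float(np.ceil(X[:, j].max()) + 1.0))
        for j, name in enumerate(names)
    }
    table = FeatureTable(
        values=X,
        missing_mask=mask,
        feature_names=names,
        feature_ranges=ranges,
    )
    return table, labels


def toy_graph(name: str, size: int) -> nx.Graph:
    """Named unit-weight fixture graph with deterministic integer node ids.

    ``star``: K_{1, size-1} with center 0; ``path``/``cycle``/``complete`` the
    obvious graphs; ``barbell`` and ``bridge_cliques``: two complete graphs of
    ``size // 2`` nodes joined by a single bridge edge.
    """
    if name == "star":
        G = nx.star_graph(size - 1)
    elif name == "path":
        G = nx.path_graph(size)
    elif name == "cycle":
        G = nx.cycle_graph(size)
    elif name == "complete":
        G = nx.complete_graph(size)
    elif name in ("barbell", "bridge_cliques"):
        if size < 4 or size % 2:
            raise ValueError("barbell needs an even size >= 4")
        G = nx.barbell_graph(size // 2, 0)
    else:
        raise ValueError(f"unknown toy graph {name!r}")
    nx.set_edge_attributes(G, 1.0, "weight")
    G.graph["tag"] = f"{name}:{size}"
    return G


# 36 synthetic feature names mimicking a six-category phenotype inventory
# (diagnostic observation/interview scores, cognition, language, behavior
# checklists, parental questionnaires). Purely synthetic; no clinical content.
PHENOTYPE_FEATURES: dict[str, tuple[float, float]] = {
    "ados_comm_social": (0, 24),
    "ados_rrb": (0, 8),
    "ados_social_affect": (0, 20),
    "adir_social": (0, 30),
    "adir_verbal": (0, 26),
    "adir_rrb": (0, 12),
    "adir_abnormality_evident": (0, 5),
    "vineland_social": (20, 140),
    "vineland_daily_living": (20, 140),
    "verbal_iq": (10, 160),
    "nonverbal_iq": (10, 160),
    "vineland_communication": (20, 140),
    "regression": (0, 1),
    "word_delay": (0, 1),
    "adir_language_level": (0, 5),
    "abc_stereotypy": (0, 21),
    "abc_lethargy": (0, 48),
    "abc_irritability": (0, 45),
    "abc_hyperactivity": (0, 48),
    "abc_inappropriate_speech": (0, 12),
    "rbs_compulsive": (0, 24),
    "rbs_self_injurious": (0, 24),
    "rbs_stereotyped": (0, 18),
    "rbs_ritualistic": (0, 18),
    "rbs_restricted": (0, 12),
    "rbs_sameness": (0, 33),
    "cbcl_internalizing": (30, 100),
    "cbcl_externalizing": (30, 100),
    "srs_awareness": (30, 110),
    "srs_cognition": (30, 110),
    "srs_communication": (30, 110),
    "srs_mannerisms": (30, 110),
    "srs_motivation": (30, 110),
    "srs_t_score": (30, 110),
    "bapq_father": (1, 6),
    "bapq_mother": (1, 6),
}

# near-duplicate pairs: the first member tracks the second with |r| ~ 0.95,
# so a 0.8 correlation filter removes exactly three features
_DUPLICATE_OF = {
    "ados_social_affect": "ados_comm_social",
    "verbal_iq": "nonverbal_iq",
    "srs_t_score": "srs_communication",
}

# ~0.1% of cells missing, concentrated in two designated features
_MISSING_HEAVY = ("bapq_father", "bapq_mother")


def phenotype_like_table(seed: int = 0, n: int = 500) -> tuple[FeatureTable, np.ndarray]:
    """A 36-feature synthetic table shaped like a phenotype severity inventory.

    Four planted subgroups of graded severity drive every feature through a
    latent severity factor (about half of each feature's variance), three
    features are near-duplicates of another so the 0.8 correlation filter
    removes exactly three, and roughly 0.1% of cells are missing with >= 90%
    of the gaps in two designated columns. Returns (table, planted labels).
    """
    rng = np.random.default_rng(seed)
    names = list(PHENOTYPE_FEATURES)
    d = len(names)
    k = 4
    proportions = np.array([0.35, 0.30, 0.20, 0.15])
    labels = rng.choice(k, size=n, p=proportions)
    labels[:k] = np.arange(k)
    severity = np.array([-1.8, -0.6, 0.6, 1.8])[labels] + rng.standard_normal(n)

    # shared-variance fraction ~0.5 keeps cross-feature |r| well below 0.8
    X = np.empty((n, d))
    col = {name: j for j, name in enumerate(names)}
    for j, name in enumerate(names):
        if name in _DUPLICATE_OF:
            continue
        lo, hi = PHENOTYPE_FEATURES[name]
        span = hi - lo
        loading = rng.uniform(0.9, 1.1)
        raw = loading * severity + rng.standard_normal(n)
        raw = (raw - raw.min()) / (raw.max() - raw.min())
        X[:, j] = lo + raw * span * rng.uniform(0.6, 0.9)
    for name, source in _DUPLICATE_OF.items():
        j, js = col[name], col[source]
        src = X[:, js]
        noise = rng.standard_normal(n) * 0.3 * src.std()
        lo, hi = PHENOTYPE_FEATURES[name]
        dup = src + noise
        dup = lo + (dup - dup.min()) / (dup.max() - dup.min()) * (hi - lo)
        X[:, j] = dup
    X = np.clip(
        X,
        [PHENOTYPE_FEATURES[m][0] for m in names],
        [PHENOTYPE_FEATURES[m][1] for m in names],
    )

    mask = np.zeros((n, d), dtype=bool)
    n_missing = max(2, int(round(0.001 * n * d)))  # ~0.1% of cells
    n_heavy = int(np.ceil(0.95 * n_missing))
    heavy_cols = [col[c] for c in _MISSING_HEAVY]
    rows = rng.choice(n, size=n_heavy, replace=False)
    for i, r in enumerate(rows):
        mask[r, heavy_cols[i % 2]] = True
    light_cols = [j for j in range(d) if j not in heavy_cols]
    for _ in range(n_missing - n_heavy):
        mask[rng.integers(n), rng.choice(light_cols)] = True

    table = FeatureTable(
        values=X,
        missing_mask=mask,
        feature_names=names,
        feature_ranges={m: PHENOTYPE_FEATURES[m] for m in names},
    )
    return table, labels


def write_truth(path: str | Path, labels: np.ndarray, sample_ids=None) -> None:
    """Planted labels as TSV: sample_id, planted_cluster, is_outlier."""
    n = len(labels)
    ids = sample_ids if sample_ids is not None else [f"s{i}" for i in range(n)]
    df = pd.DataFrame(
        {
            "sample_id": ids,
            "planted_cluster": labels,
            "is_outlier": (np.asarray(labels) < 0).astype(int),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
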