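import numpy as np
import pytest

from nbrclust import MixtureSpec, gaussian_mixture_table, knn_graph, min_connectivity
from nbrclust.preprocess import normalize_features


def ari(truth, clustering):
    """Adjusted Rand index between planted labels and a Clustering, scored on
    the labelled nodes only."""
    from sklearn.metrics import adjusted_rand_score

    nodes = sorted(clustering.labels)
    return adjusted_rand_score(
        np.asarray(truth)[nodes], [clustering.labels[v] for v in nodes]
    )


@pytest.fixture(scope="session")
def two_blob():
    """60 points in two well-separated Gaussian blobs, normalized, with graph."""
    spec = MixtureSpec(n=60, d=2, k_true=2, separation=8.0, seed=1)
    table, labels = gaussian_mixture_table(spec)
    norm = normalize_features(table)
    G = knn_graph(norm, min_connectivity(norm))
    return norm, labels, G


@pytest.fixture(scope="session")
def three_blob():
    spec = MixtureSpec(n=90, d=2, k_true=3, separation=8.0, seed=2)
    table, labels = gaussian_mixture_table(spec)
    norm = normalize_features(table)
    G = knn_graph(norm, min_connectivity(norm))
    return norm, labels, G
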