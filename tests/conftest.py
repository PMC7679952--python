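import numpy as np
import pytest

from ctcnet.connectivity import BrainGraph, ConnectivityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


def make_matrix(values, labels=None) -> ConnectivityMatrix:
    values = np.asarray(values, dtype=float)
    labels = labels or [f"r{i}" for i in range(values.shape[0])]
    return ConnectivityMatrix(labels=list(labels), values=values)


def make_graph(adjacency, labels=None, partition=None) -> BrainGraph:
    adjacency = np.asarray(adjacency, dtype=bool)
    labels = labels or [f"r{i}" for i in range(adjacency.shape[0])]
    return BrainGraph(labels=list(labels), adjacency=adjacency, partition=partition)


def random_graph(n: int, p: float, rng: np.random.Generator) -> BrainGraph:
    adj = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                adj[i, j] = adj[j, i] = True
    return make_graph(adj)


def floyd_warshall_oracle(adjacency: np.ndarray) -> np.ndarray:
    """Brute-force all-pairs hop counts, independent of scipy."""
    n = adjacency.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adjacency.astype(bool)] = 1.0
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def efficiency_oracle(adjacency: np.ndarray) -> float:
    d = floyd_warshall_oracle(adjacency)
    n = adjacency.shape[0]
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))
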