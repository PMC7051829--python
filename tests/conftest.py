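"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's solver internals:
path costs are recomputed from whole weight lists over exhaustively
enumerated simple paths, and the local association rule is re-derived
recursively, so solver results are checked against genuinely
independent computations.
"""

import numpy as np
import pytest
from hypothesis import settings

from pathclust import WeightedGraph

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


# ---------------------------------------------------------------------------
# independent oracles


def enumerate_path_optimum(graph: WeightedGraph, peaks, path_cost_fn):
    """Brute-force optimum over all simple peak-to-node paths.

    Returns (best_cost, argmin_peak_labels) per node, where the cost of
    a path is path_cost_fn(list_of_edge_weights) computed from scratch
    (no incremental state shared with the solver).  argmin_peak_labels
    is the set of peak labels achieving the minimal cost.
    """
    n = graph.n_nodes
    adj = [[] for _ in range(n)]
    for u, v, w in zip(graph.u, graph.v, graph.w):
        adj[int(u)].append((int(v), float(w)))
        adj[int(v)].append((int(u), float(w)))

    best = np.full(n, np.inf)
    argmin = [set() for _ in range(n)]

    def consider(node, label, cost):
        if cost < best[node] - 1e-15:
            best[node] = cost
            argmin[node] = {label}
        elif abs(cost - best[node]) <= 1e-12:
            argmin[node].add(label)

    def dfs(node, label, weights, visited):
        consider(node, label, path_cost_fn(weights))
        for nbr, w in adj[node]:
            if nbr not in visited:
                visited.add(nbr)
                weights.append(w)
                dfs(nbr, label, weights, visited)
                weights.pop()
                visited.remove(nbr)

    for label, pk in enumerate(peaks):
        dfs(int(pk), label, [], {int(pk)})
    return best, argmin


def cdp_oracle(rho, nearest_higher, peaks):
    """Recursive (memoized) re-derivation of the local association rule."""
    peak_label = {int(pk): lab for lab, pk in enumerate(peaks)}
    memo = {}

    def resolve(i):
        if i in memo:
            return memo[i]
        if i in peak_label:
            memo[i] = peak_label[i]
        elif nearest_higher[i] == -1:
            memo[i] = -1
        else:
            memo[i] = resolve(int(nearest_higher[i]))
        return memo[i]

    return np.array([resolve(i) for i in range(len(rho))])


def random_graph(rng, n_nodes, edge_prob=0.4):
    """Random connected-ish weighted graph with continuous weights."""
    edges = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < edge_prob:
                edges.append((i, j, rng.uniform(0.1, 5.0)))
    # spanning chain so most nodes are reachable
    order = rng.permutation(n_nodes)
    for a, b in zip(order[:-1], order[1:]):
        edges.append((min(a, b), max(a, b), rng.uniform(0.1, 5.0)))
    u, v, w = map(np.array, zip(*edges))
    return WeightedGraph(n_nodes, u, v, w)


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def het_sample():
    from pathclust import make_heterogeneous_fixture

    return make_heterogeneous_fixture(seed=0)


@pytest.fixture(scope="session")
def het_solved(het_sample):
    """Density model, peaks and full graph for the heterogeneous fixture."""
    from pathclust import (build_full_graph, compute_delta, estimate_density,
                           select_peaks_topn)

    density = estimate_density(het_sample.points)
    compute_delta(het_sample.points, density)
    peaks = select_peaks_topn(density, 2)
    graph = build_full_graph(het_sample.points)
    return density, peaks, graph


@pytest.fixture(scope="session")
def two_gauss_sample():
    from pathclust import make_gaussian_mixture_hd

    return make_gaussian_mixture_hd(2, n_per_cluster=60, n_clusters=2, seed=11)
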