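"""Weighted graph construction over point sets.

The clustering method operates on an undirected weighted graph G(V, E, w)
whose nodes are the data points and whose edge weights come from a
pluggable nonnegative dissimilarity (Euclidean, Minkowski-p, or a
Spearman-correlation-derived distance for expression-like row vectors).
Graphs may be fully connected or pruned to a union-symmetrized k-nearest-
neighbor topology; multiple edges between the same pair of nodes are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import rankdata

from .errors import ConfigError, DataError
from .points import PointSet

_TIE_RTOL = 1e-9


@dataclass
class MetricSpec:
    """Point-to-point dissimilarity used for edge weights.

    ``spearman_distance`` is defined as 1 - rho_spearman between the two
    coordinate rows, giving a symmetric dissimilarity in [0, 2].
    """

    name: str = "euclidean"
    p: float = 2.0

    def __post_init__(self) -> None:
        if self.name not in ("euclidean", "minkowski_p", "spearman_distance"):
            raise ConfigError(f"unknown metric {self.name!r}")
        if self.name == "minkowski_p" and self.p < 1:
            raise ConfigError("minkowski p must be >= 1")

    def pairwise(self, X: np.ndarray) -> np.ndarray:
        """Full symmetric distance matrix for the rows of X."""
        X = np.asarray(X, dtype=float)
        if self.name == "euclidean":
            return cdist(X, X)
        if self.name == "minkowski_p":
            return cdist(X, X, metric="minkowski", p=self.p)
        # spearman: rank each row, then 1 - Pearson correlation of ranks
        sd = X.std(axis=1)
        if np.any(sd == 0):
            bad = int(np.argwhere(sd == 0)[0, 0])
            raise DataError(
                f"spearman_distance undefined for constant row (point index {bad})"
            )
        ranks = np.apply_along_axis(rankdata, 1, X)
        rho = np.corrcoef(ranks)
        D = 1.0 - rho
        np.fill_diagonal(D, 0.0)
        return np.maximum(D, 0.0)


@dataclass
class WeightedGraph:
    """Sparse undirected multigraph with nonnegative edge weights."""

    n_nodes: int
    u: np.ndarray
    v: np.ndarray
    w: np.ndarray
    metric_tag: str = "euclidean"
    _adj: list | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=np.int64)
        self.v = np.asarray(self.v, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float)
        if not (len(self.u) == len(self.v) == len(self.w)):
            raise DataError("edge arrays must have equal length")
        if len(self.w) and (not np.isfinite(self.w).all() or self.w.min() < 0):
            raise DataError("edge weights must be finite and nonnegative")

    @property
    def n_edges(self) -> int:
        return len(self.w)

    def adjacency(self) -> list:
        """Per-node list of (neighbor_array, weight_array), both directions."""
        if self._adj is None:
            heads = np.concatenate([self.u, self.v])
            tails = np.concatenate([self.v, self.u])
            ws = np.concatenate([self.w, self.w])
            order = np.argsort(heads, kind="stable")
            heads, tails, ws = heads[order], tails[order], ws[order]
            starts = np.searchsorted(heads, np.arange(self.n_nodes + 1))
            self._adj = [
                (tails[starts[i] : starts[i + 1]], ws[starts[i] : starts[i + 1]])
                for i in range(self.n_nodes)
            ]
        return self._adj

    def to_edge_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"u": self.u, "v": self.v, "weight": self.w, "metric_tag": self.metric_tag}
        )


def build_full_graph(points: PointSet, metric: MetricSpec | None = None) -> WeightedGraph:
    """Fully connected graph: one edge per unordered point pair."""
    metric = metric or MetricSpec()
    n = points.n
    if n < 2:
        raise DataError("a graph needs at least 2 points")
    D = metric.pairwise(points.X)
    iu, ju = np.triu_indices(n, k=1)
    return WeightedGraph(n, iu, ju, D[iu, ju], metric_tag=metric.name)


def build_knn_graph(points: PointSet, k: int, metric: MetricSpec | None = None) -> WeightedGraph:
    """Union-symmetrized k-nearest-neighbor graph.

    Distance ties at rank k are all included, so the edge set is a
    deterministic superset independent of sort order.
    """
    metric = metric or MetricSpec()
    n = points.n
    if n < 2:
        raise DataError("a graph needs at least 2 points")
    if not 1 <= k < n:
        raise ConfigError(f"k must satisfy 1 <= k < n, got k={k}, n={n}")
    D = metric.pairwise(points.X)
    np.fill_diagonal(D, np.inf)
    kth = np.partition(D, k - 1, axis=1)[:, k - 1]
    thresh = kth * (1 + _TIE_RTOL) + 1e-300
    pairs = set()
    for i in range(n):
        for j in np.nonzero(D[i] <= thresh[i])[0]:
            pairs.add((min(i, int(j)), max(i, int(j))))
    if pairs:
        uu, vv = map(np.array, zip(*sorted(pairs)))
        ww = D[uu, vv]
    else:  # pragma: no cover - k >= 1 always yields edges
        uu = vv = ww = np.array([])
    return WeightedGraph(n, uu, vv, ww, metric_tag=metric.name)


def components(graph: WeightedGraph) -> np.ndarray:
    """Connected-component id per node (0-based, arbitrary but stable order)."""
    m = coo_matrix(
        (np.ones(graph.n_edges), (graph.u, graph.v)),
        shape=(graph.n_nodes, graph.n_nodes),
    )
    _, comp = connected_components(m, directed=False)
    return comp


def default_graph(points: PointSet, metric: MetricSpec | None = None) -> WeightedGraph:
    """Default topology: full graph for small n, kNN above.

    The crossover (n = 2000) and the kNN size k = max(10, ceil(0.02 n))
    follow the same 1-2% neighborhood heuristic used for the density
    bandwidth.
    """
    if points.n <= 2000:
        return build_full_graph(points, metric)
    k = max(10, int(np.ceil(0.02 * points.n)))
    return build_knn_graph(points, k, metric)
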