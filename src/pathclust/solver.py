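"""Multi-source generalized Dijkstra from density peaks.

Clustering is cast as a single-source shortest-path problem: a fictitious
source s is connected to every density peak with an edge of negligible
cost epsilon, and every point is assigned to the peak through which its
optimal s-to-point path runs.  Because the path-cost functional is
monotone under extension (extending a path never lowers its cost),
Dijkstra's algorithm yields globally optimal path costs; the fictitious
source is realized as multi-source initialization, which is equivalent
and guarantees by construction that each predecessor chain contains
exactly one peak (its root).

Three functionals are provided:

* cumulative p-norm  xi_p = (sum_e w_e^p)^(1/p)  (p = 1 is the plain
  shortest path; large p approaches minimax),
* minimax            xi_inf = max_e w_e  (the optimal path minimizes its
  largest gap -- many small hops beat one big jump),
* trained            additive accumulation where each extension is scored
  by a path-fragment classifier and invalid fragments pay a penalty.

The classic density-peak association rule (each point inherits the label
of its nearest higher-density point, chained until a peak) is provided as
the local-rule comparator, :func:`cdp_assign`.
"""

from __future__ import annotations

import heapq
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .density import DensityModel, PeakSet, _higher_order, compute_delta, otsu_threshold
from .errors import ConfigError, DataError, NonMonotoneCostError
from .graph import MetricSpec, WeightedGraph

logger = logging.getLogger(__name__)

NOISE = -1
_NO_LABEL = np.iinfo(np.int64).max


# ---------------------------------------------------------------------------
# path-cost functionals


def cumulative_cost(weights, p: float = 1.0) -> float:
    """Cost of a whole path under the cumulative p-norm: (sum w^p)^(1/p)."""
    if p < 1:
        raise ConfigError("cumulative p must be >= 1")
    w = np.asarray(weights, dtype=float)
    if len(w) == 0:
        return 0.0
    return float((w**p).sum() ** (1.0 / p))


def minimax_cost(weights, epsilon: float = 0.0) -> float:
    """Cost of a whole path under minimax: its maximum edge weight."""
    w = np.asarray(weights, dtype=float)
    if len(w) == 0:
        return float(epsilon)
    return float(w.max())


class CostFunctional:
    """Monotone path-cost functional usable by the solver.

    Subclasses maintain a scalar path state ("key") that is comparable,
    non-decreasing under :meth:`extend`, and mapped to the reported path
    cost by :meth:`cost_of`.
    """

    kind = "abstract"
    window = 0  # trailing real nodes needed before the classifier engages
    requires_density = False

    def initial(self, epsilon: float) -> float:
        raise NotImplementedError

    def extend(self, key: float, weight: float, fragment=None, density=None) -> float:
        raise NotImplementedError

    def cost_of(self, key: float) -> float:
        return key


class CumulativeCost(CostFunctional):
    """xi_p; internally Dijkstra runs on sum(w^p), a monotone transform."""

    kind = "cumulative_p"

    def __init__(self, p: float = 1.0):
        if p < 1:
            raise ConfigError("cumulative p must be >= 1")
        self.p = float(p)

    def initial(self, epsilon: float) -> float:
        return epsilon**self.p

    def extend(self, key, weight, fragment=None, density=None):
        return key + weight**self.p

    def cost_of(self, key):
        return key ** (1.0 / self.p)


class MinimaxCost(CostFunctional):
    kind = "minimax"

    def initial(self, epsilon: float) -> float:
        return epsilon

    def extend(self, key, weight, fragment=None, density=None):
        return max(key, weight)


class TrainedCost(CostFunctional):
    """Fragment-classifier cost: (invalid-fragment count, bottleneck edge).

    The path cost is lexicographic in (number of fragments classified
    invalid, maximum edge weight), encoded as count * (penalty + 1) +
    running-max (edge weights never exceed the penalty, the dataset
    diameter, so the encoding is exact).  The count can only grow and the
    running max can only rise, so the cost is monotone under extension
    AND isotone (a better prefix never yields a worse extension), which
    keeps Dijkstra globally optimal.  One invalid fragment therefore
    outweighs any clean path, and when every fragment is valid the
    functional reduces exactly to minimax.

    While the growing path has fewer than window+1 real nodes the
    classifier is bypassed and only the edge weight enters (warm-up);
    under bottleneck accumulation this bypass cannot be exploited by
    long cheap jumps, unlike under additive accumulation.
    """

    kind = "trained"
    requires_density = True

    def __init__(self, model):
        self.model = model
        self.window = int(model.window)
        self._big = float(model.penalty) + 1.0

    def initial(self, epsilon: float) -> float:
        return epsilon

    def extend(self, key, weight, fragment=None, density=None):
        import math

        count = math.floor(key / self._big + 1e-9)
        mm = key - count * self._big
        if fragment is not None and not self.model.is_valid_fragment(fragment, density):
            count += 1
        return count * self._big + max(mm, weight)


@dataclass
class SolverConfig:
    """epsilon: cost of the source-to-peak edges (0 is safe; any
    negligible positive value is admissible).  noise_cutoff: None keeps
    all assignments, 'otsu' derives the path-cost cutoff automatically,
    a float is used as-is."""

    epsilon: float = 0.0
    noise_cutoff: float | str | None = None

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ConfigError("epsilon must be >= 0")
        if isinstance(self.noise_cutoff, str) and self.noise_cutoff not in ("otsu", "auto"):
            raise ConfigError("noise_cutoff must be None, 'otsu' or a number")


@dataclass
class ClusteringResult:
    """Per-point outcome of a solve.

    labels[i] is the ordinal label of the peak rooting i's predecessor
    chain (-1 for noise / unreachable); path_cost[i] the optimal path
    cost from the source; predecessor[i] the previous node on that path
    (-1 at peaks and unassigned points).
    """

    labels: np.ndarray
    path_cost: np.ndarray
    predecessor: np.ndarray
    peak_of: dict
    hops: np.ndarray | None = None
    noise_cutoff: float | None = None

    @property
    def n(self) -> int:
        return len(self.labels)

    def path_to(self, i: int) -> list[int]:
        """Ordered node indices from the rooting peak to point i."""
        if self.labels[i] == NOISE and self.predecessor[i] == -1 and i not in self.peak_of.values():
            raise DataError(f"point {i} is unassigned; no path available")
        chain = [int(i)]
        while self.predecessor[chain[-1]] != -1:
            chain.append(int(self.predecessor[chain[-1]]))
        return chain[::-1]


def solve(graph: WeightedGraph, peaks: PeakSet, functional: CostFunctional,
          config: SolverConfig | None = None,
          density: DensityModel | None = None) -> ClusteringResult:
    """Optimal association of every reachable point to a density peak.

    Ties on path cost are broken deterministically: fewer hops, then
    lower peak label, then lower node index.
    """
    config = config or SolverConfig()
    if peaks.n_peaks == 0:
        raise DataError("cannot solve with an empty peak set")
    if functional.requires_density and density is None:
        raise ConfigError(f"functional {functional.kind!r} requires a density model")
    n = graph.n_nodes
    if peaks.peak_indices.max() >= n or peaks.peak_indices.min() < 0:
        raise DataError("peak index out of range")

    adj = graph.adjacency()
    best_key = np.full(n, np.inf)
    best_hops = np.full(n, np.iinfo(np.int64).max, dtype=np.int64)
    best_label = np.full(n, _NO_LABEL, dtype=np.int64)
    predecessor = np.full(n, -1, dtype=np.int64)
    finalized = np.zeros(n, dtype=bool)
    labels = np.full(n, NOISE, dtype=np.int64)
    hops_out = np.zeros(n, dtype=np.int64)
    win = functional.window

    heap = []
    k0 = functional.initial(config.epsilon)
    for lab, pk in enumerate(peaks.peak_indices):
        pk = int(pk)
        best_key[pk], best_hops[pk], best_label[pk] = k0, 0, lab
        heapq.heappush(heap, (k0, 0, lab, pk, -1))

    while heap:
        key, hops, lab, node, pred = heapq.heappop(heap)
        if finalized[node]:
            continue
        if (key, hops, lab) != (best_key[node], best_hops[node], best_label[node]):
            continue  # stale entry
        finalized[node] = True
        predecessor[node] = pred
        labels[node] = lab
        hops_out[node] = hops
        nbrs, ws = adj[node]
        if len(nbrs) == 0:
            continue
        frag_head = None
        if win > 0 and hops + 2 >= win + 1:
            frag_head = []
            cur = node
            for _ in range(win):
                frag_head.append(cur)
                cur = int(predecessor[cur])
            frag_head.reverse()
        for nbr, w_edge in zip(nbrs, ws):
            nbr = int(nbr)
            if finalized[nbr]:
                continue
            frag = None if frag_head is None else frag_head + [nbr]
            new_key = functional.extend(key, float(w_edge), fragment=frag, density=density)
            if new_key < key:
                raise NonMonotoneCostError(
                    f"functional {functional.kind!r} decreased the path cost "
                    f"({key} -> {new_key}) while extending"
                )
            cand = (new_key, hops + 1, lab)
            if cand < (best_key[nbr], best_hops[nbr], best_label[nbr]):
                best_key[nbr], best_hops[nbr], best_label[nbr] = cand
                heapq.heappush(heap, (new_key, hops + 1, lab, nbr, node))

    path_cost = np.array(
        [functional.cost_of(k) if np.isfinite(k) else np.inf for k in best_key]
    )
    if not finalized.all():
        n_unreached = int((~finalized).sum())
        warnings.warn(
            f"{n_unreached} points are unreachable from any peak and were labeled noise"
        )
    peak_of = {lab: int(pk) for lab, pk in enumerate(peaks.peak_indices)}
    return ClusteringResult(labels=labels, path_cost=path_cost,
                            predecessor=predecessor, peak_of=peak_of,
                            hops=hops_out)


def cdp_assign(density: DensityModel, peaks: PeakSet) -> np.ndarray:
    """Local association rule of classic density-peak clustering.

    Each point inherits the label of its nearest higher-density point,
    chained until a peak.  Chains that end at the global density maximum
    without meeting a peak are labeled noise with a warning.
    """
    if density.nearest_higher is None:
        raise DataError("DensityModel is incomplete; run compute_delta first")
    if peaks.n_peaks == 0:
        raise DataError("cannot assign with an empty peak set")
    n = density.n
    labels = np.full(n, NOISE, dtype=np.int64)
    peak_label = {int(pk): lab for lab, pk in enumerate(peaks.peak_indices)}
    order = _higher_order(density.rho)
    orphaned = 0
    for i in order:  # descending density: nearest_higher is already labeled
        i = int(i)
        if i in peak_label:
            labels[i] = peak_label[i]
        elif density.nearest_higher[i] == -1:
            orphaned += 1
        else:
            labels[i] = labels[density.nearest_higher[i]]
    if orphaned:
        warnings.warn(
            "chain(s) ended at the global density maximum, which is not a peak; "
            "affected points were labeled noise"
        )
    return labels


def cdp_assign_forced(points, density: DensityModel, peaks: PeakSet,
                      metric: MetricSpec | None = None) -> np.ndarray:
    """CDP* comparator: the local rule with arbitrary forced seeds.

    The given seeds are lifted above every other point in the density
    ordering (preserving their relative order) and nearest-higher chains
    are recomputed, so every chain terminates at a seed.
    """
    rho = density.rho.astype(float).copy()
    span = rho.max() - rho.min() + 1.0
    boosted = rho.copy()
    boosted[peaks.peak_indices] = rho.max() + 1.0 + (rho[peaks.peak_indices] - rho.min()) / span
    model = DensityModel(rho=boosted)
    compute_delta(points, model, metric=metric)
    return cdp_assign(model, peaks)


def assign_noise(result: ClusteringResult, config: SolverConfig) -> ClusteringResult:
    """Relabel points whose optimal path cost exceeds the cutoff as noise.

    'otsu'/'auto' derives the cutoff from the path-cost distribution of
    reachable points; a constant cost distribution flags nothing.
    """
    cutoff = config.noise_cutoff
    if cutoff is None:
        return result
    if isinstance(cutoff, str):
        finite = result.path_cost[np.isfinite(result.path_cost)]
        if len(finite) == 0:
            return result
        cutoff = otsu_threshold(finite)
    cutoff = float(cutoff)
    labels = result.labels.copy()
    labels[result.path_cost > cutoff] = NOISE
    return replace(result, labels=labels, noise_cutoff=cutoff)


def check_single_peak(result: ClusteringResult, peaks: PeakSet) -> bool:
    """True iff every assigned point's predecessor chain contains exactly
    one peak, at its root (the single-peak property)."""
    peak_set = set(int(p) for p in peaks.peak_indices)
    for i in range(result.n):
        if result.labels[i] == NOISE and i not in peak_set:
            continue
        chain = result.path_to(i)
        n_peaks_on_chain = sum(1 for c in chain if c in peak_set)
        if n_peaks_on_chain != 1 or chain[0] not in peak_set:
            return False
        if chain[0] != result.peak_of[int(result.labels[i])] and result.labels[i] != NOISE:
            return False
    return True
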