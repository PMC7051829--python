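"""Path solver: cost functionals, optimality, local-rule comparator, noise."""

import warnings

import numpy as np
import pytest

from pathclust import (CumulativeCost, DataError, DensityModel, MinimaxCost,
                       NonMonotoneCostError, PeakSet, PointSet, SolverConfig,
                       WeightedGraph, assign_noise, cdp_assign, check_single_peak,
                       compute_delta, cumulative_cost, estimate_density,
                       minimax_cost, solve)
from conftest import cdp_oracle, enumerate_path_optimum, random_graph


class TestCostFunctions:
    def test_cumulative_p1_is_the_plain_sum(self):
        assert cumulative_cost([3, 4], p=1) == 7

    def test_cumulative_p2_is_the_euclidean_norm(self):
        assert cumulative_cost([3, 4], p=2) == pytest.approx(5.0)

    def test_large_p_approaches_the_minimax_cost(self):
        assert cumulative_cost([3, 4], p=64) == pytest.approx(4.0, abs=0.05)
        assert minimax_cost([3, 4]) == 4.0

    def test_p_below_one_rejected(self):
        from pathclust import ConfigError

        with pytest.raises(ConfigError):
            cumulative_cost([1.0], p=0.5)

    def test_minimax_single_edge_and_plateau(self):
        assert minimax_cost([2.5]) == 2.5
        f = MinimaxCost()
        key = f.extend(f.initial(0.0), 3.0)
        assert f.extend(key, 1.0) == key  # smaller edge leaves cost unchanged

    def test_minimax_empty_path_costs_epsilon(self):
        assert minimax_cost([], epsilon=0.25) == 0.25


class TestSolve:
    def test_peaks_keep_their_own_labels_at_cost_epsilon(self):
        g = random_graph(np.random.default_rng(0), 8)
        peaks = PeakSet([2, 5])
        res = solve(g, peaks, MinimaxCost())
        assert res.labels[2] == 0 and res.labels[5] == 1
        assert res.path_cost[2] == 0 and res.path_cost[5] == 0
        assert res.predecessor[2] == -1 and res.predecessor[5] == -1

    @pytest.mark.parametrize("functional,cost_fn", [
        (MinimaxCost(), lambda ws: max(ws) if ws else 0.0),
        (CumulativeCost(1), lambda ws: sum(ws)),
        (CumulativeCost(2), lambda ws: sum(w * w for w in ws) ** 0.5),
    ])
    def test_costs_match_exhaustive_enumeration_on_random_graphs(self, functional, cost_fn):
        for seed in range(15):
            rng = np.random.default_rng(seed)
            g = random_graph(rng, int(rng.integers(4, 9)))
            peaks = PeakSet(rng.choice(g.n_nodes, size=2, replace=False))
            res = solve(g, peaks, functional)
            best, argmin = enumerate_path_optimum(g, peaks.peak_indices, cost_fn)
            assert res.path_cost == pytest.approx(best)
            for i in range(g.n_nodes):
                assert res.labels[i] in argmin[i]

    def test_cumulative_p1_equals_textbook_multisource_dijkstra(self):
        import networkx as nx
        from pathclust import build_full_graph

        rng = np.random.default_rng(7)
        pts = PointSet(rng.normal(size=(25, 2)))
        g = build_full_graph(pts)
        peaks = PeakSet([0, 13])
        res = solve(g, peaks, CumulativeCost(1))
        G = nx.Graph()
        for u, v, w in zip(g.u, g.v, g.w):
            G.add_edge(int(u), int(v), weight=float(w))
        dist, paths = nx.multi_source_dijkstra(G, {0, 13})
        for i in range(25):
            assert res.path_cost[i] == pytest.approx(dist[i])
            assert res.labels[i] == {0: 0, 13: 1}[paths[i][0]] or \
                dist[i] == pytest.approx(min(
                    nx.dijkstra_path_length(G, 0, i), nx.dijkstra_path_length(G, 13, i)))

    def test_empty_peak_set_is_an_error(self):
        g = random_graph(np.random.default_rng(1), 5)
        with pytest.raises(DataError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                solve(g, PeakSet(np.array([], dtype=int)), MinimaxCost())

    def test_non_monotone_functional_fails_fast(self):
        class Evil(MinimaxCost):
            kind = "evil"

            def extend(self, key, weight, fragment=None, density=None):
                return key - 1.0

        g = random_graph(np.random.default_rng(2), 5)
        with pytest.raises(NonMonotoneCostError, match="evil"):
            solve(g, PeakSet([0]), Evil())

    def test_unreachable_points_are_noise_with_infinite_cost(self):
        # two disconnected 2-cliques, peak only in the first
        g = WeightedGraph(4, [0, 2], [1, 3], [1.0, 1.0])
        with pytest.warns(UserWarning, match="unreachable"):
            res = solve(g, PeakSet([0]), MinimaxCost())
        assert res.labels.tolist() == [0, 0, -1, -1]
        assert np.isinf(res.path_cost[2:]).all()

    def test_deterministic_across_repeated_runs(self):
        rng = np.random.default_rng(9)
        g = random_graph(rng, 30, edge_prob=0.3)
        peaks = PeakSet([1, 4, 7])
        r1 = solve(g, peaks, MinimaxCost())
        r2 = solve(g, peaks, MinimaxCost())
        assert np.array_equal(r1.labels, r2.labels)
        assert np.array_equal(r1.predecessor, r2.predecessor)
        assert np.array_equal(r1.path_cost, r2.path_cost)

    def test_costs_non_decreasing_along_predecessor_chains(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = random_graph(rng, 20, edge_prob=0.3)
            peaks = PeakSet([0, 3])
            for functional in (MinimaxCost(), CumulativeCost(1), CumulativeCost(2)):
                res = solve(g, peaks, functional)
                for i in range(g.n_nodes):
                    chain = res.path_to(i)
                    costs = res.path_cost[chain]
                    assert (np.diff(costs) >= -1e-12).all()

    def test_single_peak_property_on_random_graphs(self):
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            g = random_graph(rng, 25, edge_prob=0.25)
            peaks = PeakSet(rng.choice(25, size=3, replace=False))
            res = solve(g, peaks, MinimaxCost())
            assert check_single_peak(res, peaks)


class TestCdpAssign:
    def _density_chain(self):
        # 5 points in a line with ascending density toward the last
        pts = PointSet(np.arange(5, dtype=float)[:, None])
        rho = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        density = DensityModel(rho=rho)
        compute_delta(pts, density)
        return density

    def test_ascending_chain_inherits_the_top_peak_label(self):
        density = self._density_chain()
        labels = cdp_assign(density, PeakSet([4]))
        assert labels.tolist() == [0] * 5

    def test_peaks_keep_their_own_labels(self):
        density = self._density_chain()
        labels = cdp_assign(density, PeakSet([2, 4]))
        assert labels[2] == 0 and labels[4] == 1

    def test_matches_recursive_oracle_on_random_sets(self):
        rng = np.random.default_rng(5)
        pts = PointSet(rng.normal(size=(50, 2)))
        density = estimate_density(pts)
        compute_delta(pts, density)
        peaks = PeakSet(rng.choice(50, size=3, replace=False))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # global max may not be a peak
            got = cdp_assign(density, peaks)
        want = cdp_oracle(density.rho, density.nearest_higher, peaks.peak_indices)
        # the global maximum may be orphaned in both implementations
        assert np.array_equal(got, want)

    def test_chain_ending_at_non_peak_maximum_is_noise(self):
        density = self._density_chain()
        with pytest.warns(UserWarning, match="global density maximum"):
            labels = cdp_assign(density, PeakSet([0]))
        assert labels[0] == 0
        # points 1..4 chain upward to the maximum (4), which is not a peak
        assert labels[1:].tolist() == [-1, -1, -1, -1]


class TestAssignNoise:
    def _result(self, costs):
        from pathclust import ClusteringResult

        n = len(costs)
        return ClusteringResult(labels=np.zeros(n, dtype=int),
                                path_cost=np.asarray(costs, dtype=float),
                                predecessor=np.full(n, -1), peak_of={0: 0})

    def test_infinite_cutoff_keeps_everything(self):
        res = assign_noise(self._result([1, 2, 3]), SolverConfig(noise_cutoff=np.inf))
        assert (res.labels == 0).all()

    def test_bimodal_costs_flag_exactly_the_high_group(self):
        rng = np.random.default_rng(0)
        costs = np.r_[rng.normal(0.1, 0.01, 40), rng.normal(10, 0.5, 10)]
        res = assign_noise(self._result(costs), SolverConfig(noise_cutoff="otsu"))
        assert (res.labels[:40] == 0).all()
        assert (res.labels[40:] == -1).all()
        assert 0.2 < res.noise_cutoff < 9

    def test_constant_costs_flag_nothing(self):
        res = assign_noise(self._result([2.0] * 10), SolverConfig(noise_cutoff="otsu"))
        assert (res.labels == 0).all()

    def test_none_cutoff_is_identity(self):
        base = self._result([1, 100.0])
        res = assign_noise(base, SolverConfig(noise_cutoff=None))
        assert res is base
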