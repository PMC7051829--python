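"""Path-fragment features, training-set generation, SVM cost model."""

import numpy as np
import pytest

from pathclust import (ConfigError, DataError, DensityModel, PathFragment,
                       PeakSet, PointSet, SolverConfig, TrainedCost,
                       WeightedGraph, compute_delta, estimate_density,
                       extract_features, generate_training_fragments,
                       load_model, read_annotations, save_model, solve, train,
                       training_set_from_fragments, write_annotations)
from pathclust.classifier import FragmentCostModel, FragmentTrainingSet


def _toy_density(rho):
    return DensityModel(rho=np.asarray(rho, dtype=float))


class TestExtractFeatures:
    def test_profile_is_normalized_by_the_dataset_maximum(self):
        d = _toy_density([4, 3, 2, 3, 4, 0.5])
        f = extract_features(PathFragment((0, 1, 2, 3, 4)), d)
        assert f.tolist() == [1.0, 0.75, 0.5, 0.75, 1.0]

    def test_all_equal_densities_give_a_constant_profile_of_ones(self):
        d = _toy_density([2, 2, 2, 2, 2])
        f = extract_features(PathFragment((0, 1, 2, 3, 4)), d)
        assert f.tolist() == [1.0] * 5

    def test_descending_fragment_gives_monotone_profile(self):
        d = _toy_density([5, 4, 3, 2, 1])
        f = extract_features(PathFragment((0, 1, 2, 3, 4)), d)
        assert (np.diff(f) < 0).all()

    def test_out_of_range_index_rejected(self):
        with pytest.raises(DataError, match="out of range"):
            extract_features(PathFragment((0, 9)), _toy_density([1, 2]))


class TestGenerateTrainingFragments:
    def test_paper_scale_generation_is_balanced(self, het_sample, het_solved):
        density, _, _ = het_solved
        ts = generate_training_fragments(het_sample.points, density,
                                         het_sample.gt_labels, 25, 25, w=4, seed=0)
        assert ts.class_balance == {"valid": 25, "invalid": 25}
        assert len(ts.fragments) == 50
        assert all(len(f) == 5 for f in ts.fragments)
        assert ts.features.shape == (50, 5)

    def test_valid_fragments_stay_in_one_cluster_invalid_span_two(self, het_sample, het_solved):
        density, _, _ = het_solved
        gt = het_sample.gt_labels
        ts = generate_training_fragments(het_sample.points, density, gt,
                                         10, 10, w=4, seed=3)
        for f in ts.fragments:
            spanned = len(set(gt[list(f.node_indices)].tolist()))
            assert spanned == 1 if f.label == "valid" else spanned >= 2

    def test_zero_valid_requested_is_an_error(self, het_sample, het_solved):
        density, _, _ = het_solved
        with pytest.raises(ConfigError):
            generate_training_fragments(het_sample.points, density,
                                        het_sample.gt_labels, 0, 25)

    def test_single_cluster_ground_truth_cannot_yield_crossings(self):
        rng = np.random.default_rng(0)
        pts = PointSet(rng.normal(size=(30, 2)))
        density = estimate_density(pts)
        compute_delta(pts, density)
        with pytest.raises(DataError, match="achievable count"):
            generate_training_fragments(pts, density, np.zeros(30, dtype=int), 5, 5)

    def test_deterministic_given_seed(self, het_sample, het_solved):
        density, _, _ = het_solved
        a = generate_training_fragments(het_sample.points, density,
                                        het_sample.gt_labels, 8, 8, seed=42)
        b = generate_training_fragments(het_sample.points, density,
                                        het_sample.gt_labels, 8, 8, seed=42)
        assert [f.node_indices for f in a.fragments] == [f.node_indices for f in b.fragments]


def _separable_training_set():
    """Valid: flat-high profiles; invalid: deep density dip."""
    rng = np.random.default_rng(1)
    valid = 0.9 + 0.05 * rng.random((25, 5))
    invalid = 0.9 + 0.05 * rng.random((25, 5))
    invalid[:, 2] = 0.05
    frags = [PathFragment(tuple(range(5)), "valid") for _ in range(25)] + \
            [PathFragment(tuple(range(5)), "invalid") for _ in range(25)]
    feats = np.vstack([valid, invalid])
    return FragmentTrainingSet(frags, feats, {"valid": 25, "invalid": 25}, scale=3.0)


class TestTrain:
    def test_separable_profiles_train_to_full_accuracy(self):
        model = train(_separable_training_set())
        assert model.training_accuracy == 1.0
        assert model.penalty == 3.0  # dataset diameter default

    def test_valid_fragments_cost_less_than_invalid_on_average(self):
        ts = _separable_training_set()
        model = train(ts)
        d = _toy_density(np.ones(5))
        costs = []
        for f, x in zip(ts.fragments, ts.features):
            valid = bool(model.is_valid(x)[0])
            costs.append((f.label, 0.3 if valid else 0.3 + model.penalty))
        mean = lambda lab: np.mean([c for l, c in costs if l == lab])
        assert mean("valid") < mean("invalid")

    def test_contradictory_labels_do_not_crash(self):
        feats = np.tile(np.linspace(0.2, 1.0, 5), (10, 1))
        frags = [PathFragment(tuple(range(5)), "valid") for _ in range(5)] + \
                [PathFragment(tuple(range(5)), "invalid") for _ in range(5)]
        ts = FragmentTrainingSet(frags, feats, {"valid": 5, "invalid": 5}, scale=1.0)
        model = train(ts)
        assert model.training_accuracy < 1.0

    def test_single_class_rejected(self):
        ts = _separable_training_set()
        for f in ts.fragments:
            f.label = "valid"
        with pytest.raises(DataError):
            train(ts)

    def test_decision_function_matches_sklearn(self):
        from sklearn.svm import SVC

        ts = _separable_training_set()
        model = train(ts)
        y = np.array([f.label == "valid" for f in ts.fragments], dtype=int)
        ref = SVC(kernel="rbf", C=10.0, gamma="scale").fit(ts.features, y)
        rng = np.random.default_rng(2)
        probe = rng.random((40, 5))
        assert np.allclose(model.decision(probe), ref.decision_function(probe))
        # at threshold 0 the classification equals SVC.predict
        model.threshold = 0.0
        assert np.array_equal(model.is_valid(probe), ref.predict(probe).astype(bool))


class TestFragmentCost:
    def test_valid_fragment_passes_the_edge_weight_through(self):
        model = train(_separable_training_set())
        d = _toy_density([0.9, 0.92, 0.91, 0.9, 0.93])
        frag = PathFragment((0, 1, 2, 3, 4))
        assert model.fragment_cost(frag, d, 0.3) == pytest.approx(0.3)

    def test_invalid_fragment_pays_the_penalty(self):
        model = train(_separable_training_set())
        d = _toy_density([0.9, 0.92, 0.05, 0.9, 0.93])
        frag = PathFragment((0, 1, 2, 3, 4))
        assert model.fragment_cost(frag, d, 0.3) == pytest.approx(0.3 + model.penalty)

    def test_cost_never_below_the_edge_weight(self):
        model = train(_separable_training_set())
        rng = np.random.default_rng(3)
        d = _toy_density(rng.random(20))
        for _ in range(30):
            frag = PathFragment(tuple(rng.choice(20, 5, replace=False)))
            w = float(rng.random())
            assert model.fragment_cost(frag, d, w) >= w


class _RecordingModel:
    """Stand-in cost model that records every fragment it is asked about."""

    penalty = 10.0
    window = 4

    def __init__(self):
        self.seen = []

    def is_valid_fragment(self, fragment, density):
        self.seen.append(tuple(fragment))
        return True


def test_warm_up_contract_scores_only_full_length_fragments():
    """The classifier must not see fragments until the growing path has
    window+1 real nodes; afterwards every scored fragment has exactly
    window+1 graph-adjacent nodes."""
    # path graph 0-1-2-...-9, peak at 0
    n = 10
    g = WeightedGraph(n, np.arange(n - 1), np.arange(1, n), np.ones(n - 1))
    model = _RecordingModel()
    res = solve(g, PeakSet([0]), TrainedCost(model), SolverConfig(),
                density=_toy_density(np.ones(n)))
    assert (res.labels == 0).all()
    assert model.seen  # engaged at all
    for frag in model.seen:
        assert len(frag) == 5
        assert all(b - a == 1 for a, b in zip(frag, frag[1:]))
    # first scored fragment ends at node 4: the path 0..4 has 5 nodes
    assert min(f[-1] for f in model.seen) == 4


def test_retraining_same_seed_reproduces_labels_end_to_end(het_sample, het_solved):
    density, peaks, graph = het_solved
    runs = []
    for _ in range(2):
        ts = generate_training_fragments(het_sample.points, density,
                                         het_sample.gt_labels, 25, 25, seed=5)
        model = train(ts)
        res = solve(graph, peaks, TrainedCost(model), SolverConfig(), density)
        runs.append(res.labels)
    assert np.array_equal(runs[0], runs[1])


class TestAnnotationsIO:
    def test_round_trip_is_exact(self, tmp_path):
        frags = [PathFragment((1, 2, 3, 4, 5), "valid"),
                 PathFragment((9, 8, 7, 6, 5), "invalid")]
        p = tmp_path / "ann.tsv"
        write_annotations(p, frags)
        back = read_annotations(p)
        assert [(f.node_indices, f.label) for f in back] == \
               [(f.node_indices, f.label) for f in frags]

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("valid\t1\t2\t3\t4\t5\nbogus_line\n")
        with pytest.raises(DataError, match="bad.tsv:2"):
            read_annotations(p)

    def test_empty_file_warns_and_returns_nothing(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("")
        with pytest.warns(UserWarning, match="no fragments"):
            assert read_annotations(p) == []

    def test_wrong_length_detected_when_requested(self, tmp_path):
        p = tmp_path / "short.tsv"
        p.write_text("valid\t1\t2\t3\n")
        with pytest.raises(DataError, match="short.tsv:1"):
            read_annotations(p, expected_length=5)


def test_model_persistence_round_trip(tmp_path, het_sample, het_solved):
    density, peaks, graph = het_solved
    ts = generate_training_fragments(het_sample.points, density,
                                     het_sample.gt_labels, 10, 10, seed=2)
    model = train(ts)
    path = tmp_path / "model.joblib"
    save_model(model, path)
    loaded = load_model(path)
    r1 = solve(graph, peaks, TrainedCost(model), SolverConfig(), density)
    r2 = solve(graph, peaks, TrainedCost(loaded), SolverConfig(), density)
    assert np.array_equal(r1.labels, r2.labels)


def test_training_set_from_annotated_fragments(het_solved):
    density, _, _ = het_solved
    frags = [PathFragment((0, 1, 2, 3, 4), "valid"),
             PathFragment((10, 11, 12, 13, 14), "invalid")]
    ts = training_set_from_fragments(frags, density, scale=2.0)
    assert ts.features.shape == (2, 5)
    with pytest.raises(DataError, match="mixed lengths"):
        training_set_from_fragments(
            [PathFragment((0, 1), "valid"), PathFragment((0, 1, 2), "invalid")], density)
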