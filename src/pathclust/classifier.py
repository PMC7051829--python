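"""Trainable path-cost component.

A growing path is scored through its trailing *fragment* of w+1 nodes
(default 5).  The fragment's feature vector is its *density profile* --
the ordered local densities of its nodes, normalized by the dataset's
maximum density so a model transfers across rescaled datasets.  An
RBF-kernel support-vector classifier is trained on examples of valid
(within-cluster) and invalid (boundary-crossing) fragments; at solve
time a fragment classified invalid pays an additive penalty (by default
the dataset diameter, so a single invalid step outweighs any clean
path), which keeps the accumulated path cost monotone.

Training fragments can be generated automatically from a ground-truth
labeling (nearest-neighbor walks inside one cluster for the valid class,
walks forced across a cluster boundary for the invalid class) or read
from an annotation TSV produced by manual inspection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .density import DensityModel
from .errors import ConfigError, DataError
from .points import PointSet

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 4  # w; fragments have w+1 = 5 nodes


@dataclass
class PathFragment:
    node_indices: tuple
    label: str = "unlabeled"  # valid | invalid | unlabeled

    def __post_init__(self) -> None:
        self.node_indices = tuple(int(i) for i in self.node_indices)
        if self.label not in ("valid", "invalid", "unlabeled"):
            raise DataError(f"unknown fragment label {self.label!r}")

    def __len__(self) -> int:
        return len(self.node_indices)


@dataclass
class FragmentTrainingSet:
    fragments: list
    features: np.ndarray
    class_balance: dict
    scale: float = 1.0  # dataset diameter, carried for the default penalty


def extract_features(fragment: PathFragment, density: DensityModel,
                     normalize: bool = True) -> np.ndarray:
    """Density profile of a fragment: ordered node densities, divided by
    the dataset's maximum density (all-zero densities map to all-ones)."""
    idx = np.asarray(fragment.node_indices)
    if idx.min() < 0 or idx.max() >= density.n:
        raise DataError(f"fragment node index out of range: {fragment.node_indices}")
    profile = density.rho[idx].astype(float)
    if not normalize:
        return profile
    top = density.rho.max()
    if top <= 0:
        return np.ones_like(profile)
    return profile / top


def _nn_walk(D: np.ndarray, start: int, allowed: np.ndarray, length: int,
             rng=None, spread: int = 1) -> list[int] | None:
    """Near-neighbor walk of `length` nodes inside `allowed`.

    With spread > 1 and an rng, each step picks uniformly among the
    `spread` nearest unvisited candidates instead of strictly the
    nearest, which diversifies the sampled density profiles.
    """
    walk = [start]
    used = {start}
    while len(walk) < length:
        row = D[walk[-1]].copy()
        row[~allowed] = np.inf
        row[list(used)] = np.inf
        finite = np.isfinite(row)
        if not finite.any():
            return None
        if rng is not None and spread > 1:
            cands = np.argsort(row)[: min(spread, int(finite.sum()))]
            nxt = int(cands[rng.integers(len(cands))])
        else:
            nxt = int(np.argmin(row))
        walk.append(nxt)
        used.add(nxt)
    return walk


def generate_training_fragments(points: PointSet, density: DensityModel,
                                gt_labels: np.ndarray, n_valid: int = 25,
                                n_invalid: int = 25, w: int = DEFAULT_WINDOW,
                                seed: int = 0) -> FragmentTrainingSet:
    """Sample labeled fragments from a ground truth.

    Valid fragments are nearest-neighbor walks of w+1 nodes entirely
    inside one ground-truth cluster; invalid fragments walk inside one
    cluster, then jump to the nearest point of a different label and
    continue there, so their node set spans >= 2 labels (background -1
    counts as a label of its own, which yields noise-crossing examples).
    """
    if n_valid < 1 or n_invalid < 1:
        raise ConfigError("n_valid and n_invalid must both be >= 1")
    if w < 1:
        raise ConfigError("fragment window w must be >= 1")
    gt = np.asarray(gt_labels)
    if len(gt) != points.n:
        raise DataError("ground-truth labels and points have different lengths")
    rng = np.random.default_rng(seed)
    D = cdist(points.X, points.X)
    np.fill_diagonal(D, np.inf)
    length = w + 1
    labels_present = np.unique(gt)
    cluster_labels = [l for l in labels_present if l != -1 and (gt == l).sum() >= length]
    if not cluster_labels:
        raise DataError(f"no ground-truth cluster has >= {length} points")

    fragments: list[PathFragment] = []
    # valid: within-cluster walks from random starts
    attempts = 0
    while sum(f.label == "valid" for f in fragments) < n_valid:
        if attempts > 50 * n_valid:
            raise DataError(
                f"could only generate {sum(f.label == 'valid' for f in fragments)} "
                f"of {n_valid} valid fragments"
            )
        attempts += 1
        lab = cluster_labels[rng.integers(len(cluster_labels))]
        members = np.nonzero(gt == lab)[0]
        start = int(members[rng.integers(len(members))])
        walk = _nn_walk(D, start, gt == lab, length, rng=rng, spread=3)
        if walk is not None:
            fragments.append(PathFragment(tuple(walk), "valid"))

    # invalid: walk inside one label, jump to the nearest foreign point,
    # continue inside the foreign label; the jump position is randomized
    # over the fragment so crossings are seen at every offset
    if len(labels_present) < 2:
        raise DataError(
            "invalid-fragment sampling needs >= 2 ground-truth labels; "
            "achievable count: 0"
        )
    attempts = 0
    while sum(f.label == "invalid" for f in fragments) < n_invalid:
        got = sum(f.label == "invalid" for f in fragments)
        if attempts > 200 * n_invalid:
            raise DataError(
                f"could only generate {got} of {n_invalid} boundary-crossing fragments"
            )
        attempts += 1
        n_inside = int(rng.integers(1, length))  # 1 .. w
        lab = labels_present[rng.integers(len(labels_present))]
        members = np.nonzero(gt == lab)[0]
        if len(members) < n_inside:
            continue
        # bias starts toward the boundary: points of this label closest to a foreign point
        foreign = gt != lab
        if not foreign.any():
            continue
        d_foreign = D[np.ix_(members, np.nonzero(foreign)[0])].min(axis=1)
        m = max(1, len(members) // 4)
        near_boundary = members[np.argsort(d_foreign)[:m]]
        start = int(near_boundary[rng.integers(len(near_boundary))])
        head = _nn_walk(D, start, gt == lab, n_inside, rng=rng, spread=2)
        if head is None:
            continue
        row = D[head[-1]].copy()
        row[~foreign] = np.inf
        row[head] = np.inf
        jump = int(np.argmin(row))
        if not np.isfinite(row[jump]):
            continue
        tail_lab = gt[jump]
        tail = _nn_walk(D, jump, gt == tail_lab, length - n_inside, rng=rng, spread=2)
        if tail is None or set(tail) & set(head):
            continue
        walk = head + tail
        assert len(set(gt[list(walk)])) >= 2
        fragments.append(PathFragment(tuple(walk), "invalid"))

    feats = np.vstack([extract_features(f, density) for f in fragments])
    balance = {
        "valid": sum(f.label == "valid" for f in fragments),
        "invalid": sum(f.label == "invalid" for f in fragments),
    }
    return FragmentTrainingSet(fragments, feats, balance, scale=points.diameter())


def training_set_from_fragments(fragments: list[PathFragment], density: DensityModel,
                                scale: float = 1.0) -> FragmentTrainingSet:
    """Build a training set from externally annotated fragments."""
    if not fragments:
        raise DataError("no fragments to train on")
    lengths = {len(f) for f in fragments}
    if len(lengths) != 1:
        raise DataError(f"fragments have mixed lengths {sorted(lengths)}")
    feats = np.vstack([extract_features(f, density) for f in fragments])
    balance = {
        "valid": sum(f.label == "valid" for f in fragments),
        "invalid": sum(f.label == "invalid" for f in fragments),
    }
    return FragmentTrainingSet(list(fragments), feats, balance, scale=scale)


@dataclass
class FragmentCostModel:
    """Fitted path-fragment classifier with its cost mapping.

    ``step_cost`` returns the base edge weight when the fragment is
    classified valid and base + penalty otherwise; the penalty is
    strictly positive, so the accumulated (additive) path cost is
    monotone under extension.
    """

    _sv: np.ndarray = field(repr=False)
    _dual_coef: np.ndarray = field(repr=False)
    _intercept: float
    _gamma: float
    _valid_sign: float
    penalty: float
    window: int = DEFAULT_WINDOW
    normalize: bool = True
    training_accuracy: float | None = None
    threshold: float = 0.0

    def decision(self, profiles: np.ndarray) -> np.ndarray:
        """SVC decision values, vectorized over fragment profiles.

        Re-implements the fitted RBF SVC's decision function from its
        support vectors and dual coefficients: per-call overhead of the
        scikit-learn predict path would dominate the solver otherwise.
        Agreement with ``SVC.predict`` is asserted in the test suite.
        """
        P = np.atleast_2d(np.asarray(profiles, dtype=float))
        sq = ((P[:, None, :] - self._sv[None, :, :]) ** 2).sum(axis=2)
        return np.exp(-self._gamma * sq) @ self._dual_coef + self._intercept

    def is_valid(self, profiles: np.ndarray) -> np.ndarray:
        return self.decision(profiles) * self._valid_sign > self.threshold

    def fragment_cost(self, fragment: PathFragment, density: DensityModel,
                      base_edge_weight: float) -> float:
        if base_edge_weight < 0:
            raise DataError("base edge weight must be >= 0")
        profile = extract_features(fragment, density, normalize=self.normalize)
        if bool(self.is_valid(profile)[0]):
            return float(base_edge_weight)
        return float(base_edge_weight) + self.penalty

    def is_valid_fragment(self, fragment, density: DensityModel) -> bool:
        """Classify a bare node-index sequence (the solver's hot path)."""
        profile = density.rho[np.asarray(fragment)].astype(float)
        if self.normalize:
            top = density.rho.max()
            profile = profile / top if top > 0 else np.ones_like(profile)
        return bool(self.is_valid(profile)[0])

    def step_cost(self, fragment, density: DensityModel, base_edge_weight: float) -> float:
        """Additive mapping on a bare node-index sequence: base edge
        weight if valid, base + penalty if invalid."""
        if self.is_valid_fragment(fragment, density):
            return float(base_edge_weight)
        return float(base_edge_weight) + self.penalty


def train(training: FragmentTrainingSet, penalty: float | None = None,
          C: float = 10.0) -> FragmentCostModel:
    """Fit the RBF support-vector fragment classifier.

    penalty defaults to the training set's dataset diameter.  The fit is
    deterministic for a fixed training set (binary SVC has no random
    component at these sizes).

    The decision threshold is shifted below the smallest decision value
    of any valid training fragment: mistaking a valid fragment for
    invalid blocks legitimate paths (a regression relative to the
    untrained cost), whereas missing a crossing merely forgoes an
    improvement, so the operating point favors valid-class recall.
    """
    from sklearn.svm import SVC

    y = np.array([f.label for f in training.fragments])
    if set(y) != {"valid", "invalid"}:
        raise DataError("training set must contain both valid and invalid fragments")
    X = training.features
    clf = SVC(kernel="rbf", C=C, gamma="scale")
    clf.fit(X, (y == "valid").astype(int))
    acc = float(clf.score(X, (y == "valid").astype(int)))
    logger.info("fragment classifier training accuracy: %.3f", acc)
    dec = clf.decision_function(X)
    spread = dec.max() - dec.min()
    thr = float(min(0.0, dec[y == "valid"].min()) - 0.2 * spread)
    if penalty is None:
        penalty = training.scale
    if penalty <= 0:
        raise ConfigError("penalty must be positive")
    # binary SVC: decision_function > 0 <=> class 1 (valid)
    gamma_val = clf._gamma if hasattr(clf, "_gamma") else 1.0 / (X.shape[1] * X.var())
    model = FragmentCostModel(
        _sv=clf.support_vectors_.copy(),
        _dual_coef=clf.dual_coef_.ravel().copy(),
        _intercept=float(clf.intercept_[0]),
        _gamma=float(gamma_val),
        _valid_sign=1.0,
        penalty=float(penalty),
        window=len(training.fragments[0]) - 1,
        training_accuracy=acc,
        threshold=thr,
    )
    # cross-check the fast decision path against the fitted estimator once
    ref = clf.decision_function(X)
    ours = model.decision(X)
    if not np.allclose(ref, ours, atol=1e-8):
        raise RuntimeError("internal decision-function mismatch")  # pragma: no cover
    return model


def save_model(model: FragmentCostModel, path) -> None:
    """Persist a fitted fragment-cost model to a single file."""
    import joblib

    joblib.dump({"format_version": 1, "model": model}, path)


def load_model(path) -> FragmentCostModel:
    import joblib

    blob = joblib.load(path)
    if not isinstance(blob, dict) or "model" not in blob:
        raise DataError(f"{path} is not a fragment-cost model file")
    return blob["model"]


# ---------------------------------------------------------------------------
# annotation file round-trip (TSV: label <TAB> node ids)


def write_annotations(path, fragments: list[PathFragment]) -> None:
    with open(path, "w") as fh:
        for f in fragments:
            fh.write("\t".join([f.label] + [str(i) for i in f.node_indices]) + "\n")


def read_annotations(path, expected_length: int | None = None) -> list[PathFragment]:
    """Read labeled fragments; malformed rows raise with their line number."""
    fragments = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise DataError(f"{path}:{lineno}: expected label + >=2 node ids")
            label, raw = parts[0], parts[1:]
            if label not in ("valid", "invalid"):
                raise DataError(f"{path}:{lineno}: unknown label {label!r}")
            if expected_length is not None and len(raw) != expected_length:
                raise DataError(
                    f"{path}:{lineno}: expected {expected_length} node ids, got {len(raw)}"
                )
            try:
                idx = tuple(int(t) for t in raw)
            except ValueError as e:
                raise DataError(f"{path}:{lineno}: non-integer node id") from e
            fragments.append(PathFragment(idx, label))
    if not fragments:
        warnings.warn(f"{path}: no fragments found")
    return fragments
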