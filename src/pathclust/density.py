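"""Local density, delta distances, and density-peak selection.

Each point v gets a local density rho_v (Gaussian-kernel weighted neighbor
count, or a hard count within a cutoff), and a delta_v: the distance to the
nearest point of strictly higher density.  Points where both rho and delta
are large sit at the top of well-separated density modes and are selected
as cluster seeds (density peaks), either by thresholds (tau_rho, tau_delta)
or by ranking gamma = rho * delta and taking the top N.

Exact density ties are broken by point index (the lower index counts as
"higher"), which makes the higher-density relation a total order and keeps
delta well defined on gridded or duplicated data.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError
from .graph import MetricSpec
from .points import PointSet

logger = logging.getLogger(__name__)


@dataclass
class DensityConfig:
    """Density-estimation settings.

    d_c is the kernel bandwidth (Gaussian) or cutoff radius (hard count),
    in coordinate units.  When unset it is resolved from the data as the
    ``neighbor_fraction`` quantile of all pairwise distances, so the mean
    neighbor count within d_c is about neighbor_fraction * n (the 1-2%
    rule of thumb; default 0.02).
    """

    kernel: str = "gaussian"
    d_c: float | None = None
    neighbor_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "hard_count"):
            raise ConfigError(f"unknown kernel {self.kernel!r}")
        if self.d_c is not None and self.d_c <= 0:
            raise ConfigError("d_c must be positive")
        if not 0 < self.neighbor_fraction <= 1:
            raise ConfigError("neighbor_fraction must be in (0, 1]")


@dataclass
class DensityModel:
    """Per-point density quantities.

    ``nearest_higher`` holds the index of the closest strictly-higher-
    density point, with -1 as the sentinel for the global density maximum,
    whose delta is set by convention to its maximum distance to any other
    point.
    """

    rho: np.ndarray
    delta: np.ndarray | None = None
    nearest_higher: np.ndarray | None = None
    gamma: np.ndarray | None = None
    d_c: float | None = None

    @property
    def n(self) -> int:
        return len(self.rho)


@dataclass
class PeakSet:
    peak_indices: np.ndarray
    tau_rho: float | None = None
    tau_delta: float | None = None
    method: str = "manual"

    def __post_init__(self) -> None:
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.int64)
        if len(np.unique(self.peak_indices)) != len(self.peak_indices):
            raise DataError("peak indices must be unique")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_indices)


def resolve_dc(points: PointSet, config: DensityConfig,
               metric: MetricSpec | None = None) -> float:
    """Resolve the bandwidth: explicit d_c wins, else the quantile rule."""
    if config.d_c is not None:
        return float(config.d_c)
    if points.n < 2:
        raise ConfigError("cannot auto-resolve d_c with fewer than 2 points")
    metric = metric or MetricSpec()
    D = metric.pairwise(points.X)
    iu, ju = np.triu_indices(points.n, k=1)
    dists = D[iu, ju]
    dc = float(np.quantile(dists, config.neighbor_fraction))
    if dc <= 0:
        positive = dists[dists > 0]
        if len(positive) == 0:
            raise DataError("all points coincide; density is undefined")
        dc = float(positive.min())
    return dc


def estimate_density(points: PointSet, config: DensityConfig | None = None,
                     metric: MetricSpec | None = None) -> DensityModel:
    """Local density per point.

    gaussian:   rho_i = sum_{j != i} exp(-(d_ij / d_c)^2)
    hard_count: rho_i = #{ j != i : d_ij < d_c }
    """
    config = config or DensityConfig()
    metric = metric or MetricSpec()
    if points.n == 0:
        raise DataError("empty point set")
    if points.n == 1:
        return DensityModel(rho=np.zeros(1), d_c=config.d_c)
    dc = resolve_dc(points, config, metric)
    D = metric.pairwise(points.X)
    if config.kernel == "gaussian":
        K = np.exp(-((D / dc) ** 2))
        np.fill_diagonal(K, 0.0)
        rho = K.sum(axis=1)
    else:
        inside = D < dc
        np.fill_diagonal(inside, False)
        rho = inside.sum(axis=1).astype(float)
    return DensityModel(rho=rho, d_c=dc)


def _higher_order(rho: np.ndarray) -> np.ndarray:
    """Indices sorted from 'highest' to 'lowest' density under the
    index tie-break (lower index ranks higher on exact ties)."""
    return np.lexsort((np.arange(len(rho)), -rho))


def compute_delta(points: PointSet, model: DensityModel,
                  metric: MetricSpec | None = None) -> DensityModel:
    """Fill delta, nearest_higher and gamma = rho * delta in place.

    delta_v = min distance from v to any strictly-higher-density point;
    the global maximum gets max distance to any other point and
    nearest_higher = -1.
    """
    n = points.n
    if n < 2:
        raise DataError("compute_delta needs at least 2 points")
    rho = model.rho
    metric = metric or MetricSpec()
    D = metric.pairwise(points.X)
    order = _higher_order(rho)
    delta = np.empty(n)
    nearest = np.empty(n, dtype=np.int64)
    top = order[0]
    delta[top] = D[top].max()
    nearest[top] = -1
    for r in range(1, n):
        i = order[r]
        higher = order[:r]
        row = D[i, higher]
        j = int(np.argmin(row))
        delta[i] = row[j]
        nearest[i] = higher[j]
    model.delta = delta
    model.nearest_higher = nearest
    model.gamma = rho * delta
    return model


def select_peaks_threshold(model: DensityModel, tau_rho: float | None = None,
                           tau_delta: float | None = None) -> PeakSet:
    """Density peaks: points with rho > tau_rho AND delta > tau_delta
    (strict).  Unset thresholds default to Otsu on rho / delta."""
    if model.delta is None:
        raise DataError("DensityModel is incomplete; run compute_delta first")
    if tau_rho is None:
        tau_rho = otsu_threshold(model.rho)
    if tau_delta is None:
        tau_delta = otsu_threshold(model.delta)
    mask = (model.rho > tau_rho) & (model.delta > tau_delta)
    idx = np.nonzero(mask)[0]
    if len(idx) == 0:
        warnings.warn("peak selection returned an empty set; solving requires >= 1 peak")
    return PeakSet(idx, tau_rho=float(tau_rho), tau_delta=float(tau_delta),
                   method="threshold")


def select_peaks_topn(model: DensityModel, n_peaks: int) -> PeakSet:
    """Top-N points by gamma = rho * delta, ties broken by point index."""
    if model.gamma is None:
        raise DataError("DensityModel is incomplete; run compute_delta first")
    n = model.n
    if not 1 <= n_peaks <= n:
        raise ConfigError(f"n_peaks must be in [1, {n}], got {n_peaks}")
    order = np.lexsort((np.arange(n), -model.gamma))
    return PeakSet(np.sort(order[:n_peaks]), method="top_n")


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu's between-class-variance threshold on a 256-bin histogram.

    Shared by peak selection and the noise path-cost cutoff.  When the
    variance curve has a plateau of maximal values (well-separated
    bimodal data leaves every split inside the gap equivalent), the
    midpoint of the plateau is returned, so the threshold lands mid-gap
    rather than hugging one mode.  A constant input is degenerate: the
    constant itself is returned, so nothing lies strictly above it.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 1:
        raise DataError("otsu_threshold needs at least one finite value")
    if values.max() == values.min():
        return float(values.max())
    hist, edges = np.histogram(values, bins=256)
    hist = hist.astype(float)
    centers = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(hist)[:-1]
    w1 = hist.sum() - w0
    sum0 = np.cumsum(hist * centers)[:-1]
    total = (hist * centers).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        m0 = sum0 / w0
        m1 = (total - sum0) / w1
        var = w0 * w1 * (m0 - m1) ** 2
    var[~np.isfinite(var)] = -np.inf
    best = var.max()
    maximal = np.nonzero(var >= best * (1 - 1e-12))[0]
    # split after bin i -> class boundary at edges[i + 1]
    return float((edges[maximal[0] + 1] + edges[maximal[-1] + 1]) / 2)


def density_distance_table(model: DensityModel, ids=None):
    """Density-distance plot data (id, rho, delta, gamma) for manual
    peak inspection, as a DataFrame."""
    import pandas as pd

    if model.delta is None:
        raise DataError("DensityModel is incomplete; run compute_delta first")
    if ids is None:
        ids = np.arange(model.n)
    return pd.DataFrame(
        {"id": ids, "rho": model.rho, "delta": model.delta, "gamma": model.gamma}
    )
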