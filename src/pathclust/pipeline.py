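"""High-level clustering pipeline: density -> peaks -> graph -> solve -> noise.

This is the one-call entry point the CLI and the examples use; each stage
can also be driven separately through the underlying modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .classifier import load_model
from .density import (DensityConfig, DensityModel, PeakSet, compute_delta,
                      estimate_density, select_peaks_threshold, select_peaks_topn)
from .errors import ConfigError
from .graph import MetricSpec, WeightedGraph, build_full_graph, build_knn_graph, default_graph
from .io import RunConfig
from .points import PointSet
from .solver import (ClusteringResult, CostFunctional, CumulativeCost, MinimaxCost,
                     SolverConfig, TrainedCost, assign_noise, solve)

logger = logging.getLogger(__name__)


@dataclass
class PipelineOutput:
    result: ClusteringResult
    density: DensityModel
    peaks: PeakSet
    graph: WeightedGraph


def make_functional(config: RunConfig, model=None) -> CostFunctional:
    if config.cost == "minimax":
        return MinimaxCost()
    if config.cost == "cumulative":
        return CumulativeCost(config.p)
    if config.cost == "trained":
        if model is None:
            if config.model_path is None:
                raise ConfigError("trained cost requires a model or model_path")
            model = load_model(config.model_path)
        return TrainedCost(model)
    raise ConfigError(f"unknown cost {config.cost!r}")


def cluster_points(points: PointSet, config: RunConfig | None = None,
                   model=None) -> PipelineOutput:
    """Run the full pipeline on a point set with a resolved RunConfig."""
    config = config or RunConfig()
    metric = MetricSpec(config.metric, p=config.minkowski_p)
    dcfg = DensityConfig(kernel=config.kernel, d_c=config.d_c,
                         neighbor_fraction=config.neighbor_fraction)
    density = estimate_density(points, dcfg, metric)
    compute_delta(points, density, metric)

    if config.peak_mode == "top_n":
        if config.n_peaks is None:
            raise ConfigError("peak_mode=top_n requires n_peaks")
        peaks = select_peaks_topn(density, config.n_peaks)
    elif config.peak_mode == "threshold":
        peaks = select_peaks_threshold(density, config.tau_rho, config.tau_delta)
    else:
        raise ConfigError(f"unknown peak_mode {config.peak_mode!r}")

    if config.topology == "full":
        graph = build_full_graph(points, metric)
    elif config.topology == "knn":
        k = config.k or max(10, int(np.ceil(0.02 * points.n)))
        graph = build_knn_graph(points, k, metric)
    elif config.topology == "auto":
        graph = default_graph(points, metric)
    else:
        raise ConfigError(f"unknown topology {config.topology!r}")

    functional = make_functional(config, model=model)
    solver_cfg = SolverConfig(noise_cutoff=config.noise)
    result = solve(graph, peaks, functional, solver_cfg, density)
    result = assign_noise(result, solver_cfg)
    logger.info("clustered %d points into %d clusters (%d noise)",
                points.n, len(set(result.labels[result.labels >= 0].tolist())),
                int((result.labels < 0).sum()))
    return PipelineOutput(result=result, density=density, peaks=peaks, graph=graph)
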