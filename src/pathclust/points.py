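"""Core point-set container.

A :class:`PointSet` is the in-memory representation of a delimited numeric
point table: one string id per point plus a row of coordinates, with an
optional ground-truth label vector (``-1`` denotes background / noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DataError


@dataclass
class PointSet:
    """n points in d dimensions with ids and optional ground-truth labels."""

    X: np.ndarray
    ids: np.ndarray | None = None
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise DataError(f"coordinate array must be 2-D, got shape {self.X.shape}")
        if not np.isfinite(self.X).all():
            bad = int(np.argwhere(~np.isfinite(self.X).all(axis=1))[0, 0])
            raise DataError(f"non-finite coordinates at point index {bad}")
        if self.ids is None:
            self.ids = np.array([str(i) for i in range(len(self.X))], dtype=object)
        else:
            self.ids = np.asarray(self.ids, dtype=object)
            if len(self.ids) != len(self.X):
                raise DataError("ids and coordinates have different lengths")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int)
            if len(self.labels) != len(self.X):
                raise DataError("labels and coordinates have different lengths")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    def diameter(self) -> float:
        """Largest pairwise Euclidean distance (bounding-box based upper
        bound is deliberately not used: the exact diameter feeds the
        trained-cost penalty)."""
        from scipy.spatial.distance import pdist

        if self.n < 2:
            return 0.0
        return float(pdist(self.X).max())

    def bbox_diagonal(self) -> float:
        if self.n == 0:
            return 0.0
        span = self.X.max(axis=0) - self.X.min(axis=0)
        return float(np.sqrt((span**2).sum()))
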