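"""File formats, image pointization and heartbeat features.

The native point-table dialect is the ClustEval-style TSV: one row per
point, id first, tab-separated coordinates, no header.  CSV files with a
header row are also accepted on read (first column id, remaining numeric
columns coordinates, an optional ``label`` column as ground truth).  The
writer always emits the TSV dialect with full-precision floats so a
write/read round trip is exact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError
from .points import PointSet

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# point tables


def read_points(path, with_labels: bool = False) -> PointSet:
    """Read a point table (TSV dialect, or headered CSV).

    with_labels: treat the last (TSV) or ``label``-named (CSV) column as
    an integer ground-truth label.
    """
    path = str(path)
    with open(path) as fh:
        lines = [l.rstrip("\n") for l in fh]
    lines = [l for l in lines if l.strip()]
    if not lines:
        raise DataError(f"{path}: empty file")
    if "\t" in lines[0]:
        return _read_tsv(path, lines, with_labels)
    return _read_csv(path, lines, with_labels)


def _read_tsv(path, lines, with_labels):
    ids, rows, labels = [], [], []
    width = None
    for lineno, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if width is None:
            width = len(parts)
            if width < 2:
                raise DataError(f"{path}:{lineno}: need an id plus >= 1 coordinate")
        elif len(parts) != width:
            raise DataError(
                f"{path}:{lineno}: ragged row ({len(parts)} fields, expected {width})"
            )
        ids.append(parts[0])
        coord_part = parts[1:-1] if with_labels else parts[1:]
        try:
            rows.append([float(t) for t in coord_part])
        except ValueError:
            raise DataError(f"{path}:{lineno}: non-numeric coordinate") from None
        if with_labels:
            try:
                labels.append(int(float(parts[-1])))
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer label") from None
    return PointSet(np.array(rows), ids=np.array(ids, dtype=object),
                    labels=np.array(labels) if with_labels else None)


def _read_csv(path, lines, with_labels):
    import csv
    import io as _io

    reader = csv.reader(_io.StringIO("\n".join(lines)))
    header = next(reader)
    cols = [h.strip() for h in header]
    label_col = None
    if "label" in [c.lower() for c in cols]:
        label_col = [c.lower() for c in cols].index("label")
    ids, rows, labels = [], [], []
    for lineno, parts in enumerate(reader, start=2):
        if not parts:
            continue
        if len(parts) != len(cols):
            raise DataError(f"{path}:{lineno}: ragged row")
        ids.append(parts[0])
        try:
            rows.append([
                float(v) for i, v in enumerate(parts) if i != 0 and i != label_col
            ])
        except ValueError:
            raise DataError(f"{path}:{lineno}: non-numeric coordinate") from None
        if label_col is not None:
            labels.append(int(float(parts[label_col])))
    if not rows:
        raise DataError(f"{path}: no data rows")
    want_labels = with_labels or label_col is not None
    return PointSet(np.array(rows), ids=np.array(ids, dtype=object),
                    labels=np.array(labels) if (want_labels and labels) else None)


def write_points(path, points: PointSet, with_labels: bool = False) -> None:
    """Write the TSV dialect (id, coordinates[, label]); exact round trip."""
    with open(path, "w") as fh:
        for i in range(points.n):
            fields = [str(points.ids[i])] + [format(c, ".17g") for c in points.X[i]]
            if with_labels:
                if points.labels is None:
                    raise DataError("point set has no labels to write")
                fields.append(str(int(points.labels[i])))
            fh.write("\t".join(fields) + "\n")


def read_labels(path, fmt: str = "auto") -> np.ndarray:
    """Read a per-point label vector from one of the package's formats.

    fmt='labels': id <TAB> label rows (label in column 2);
    fmt='result': clustering output (id, label, path_cost, predecessor);
    fmt='points': point table with a trailing label column;
    fmt='auto': column 2 for 2-column files, trailing column otherwise.
    """
    if fmt not in ("auto", "labels", "result", "points"):
        raise DataError(f"unknown label format {fmt!r}")
    labels = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if fmt in ("labels", "result"):
                col = 1
            elif fmt == "points":
                col = len(parts) - 1
            else:
                col = 1 if len(parts) == 2 else len(parts) - 1
            if col >= len(parts):
                raise DataError(f"{path}:{lineno}: expected >= 2 columns")
            try:
                labels.append(int(float(parts[col])))
            except ValueError:
                raise DataError(f"{path}:{lineno}: non-integer label") from None
    return np.array(labels, dtype=int)


def write_result(path, points: PointSet, result) -> None:
    """Clustering output TSV: id, label, path_cost, predecessor."""
    with open(path, "w") as fh:
        for i in range(points.n):
            fh.write("\t".join([
                str(points.ids[i]),
                str(int(result.labels[i])),
                format(float(result.path_cost[i]), ".17g"),
                str(int(result.predecessor[i])),
            ]) + "\n")


def write_provenance(path, config: dict) -> None:
    """Sidecar JSON recording everything needed to reproduce an output."""
    from . import __version__

    blob = dict(config)
    blob["pathclust_version"] = __version__
    with open(path, "w") as fh:
        json.dump(blob, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


# ---------------------------------------------------------------------------
# images


def load_image(path) -> np.ndarray:
    path = str(path)
    if path.lower().endswith((".tif", ".tiff")):
        import tifffile

        return np.asarray(tifffile.imread(path))
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def image_to_points(image, mask=None, threshold: float | None = None) -> PointSet:
    """One point per foreground pixel at 0-based (row, col).

    Foreground is the positive part of ``mask`` when given, else pixels
    strictly above ``threshold``.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise DataError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if mask is not None:
        fg = np.asarray(mask) > 0
        if fg.shape != img.shape:
            raise DataError("mask shape does not match image shape")
    elif threshold is not None:
        fg = img > threshold
    else:
        raise DataError("either a mask or a threshold is required")
    rr, cc = np.nonzero(fg)
    if len(rr) == 0:
        raise DataError("empty foreground: no pixels selected")
    return PointSet(np.c_[rr, cc].astype(float))


def labels_to_image(points: PointSet, labels, shape) -> np.ndarray:
    """Integer label image: 0 = background and noise, clusters 1..K."""
    labels = np.asarray(labels, dtype=int)
    if len(labels) != points.n:
        raise DataError("labels and points have different lengths")
    out = np.zeros(shape, dtype=np.int32)
    rr = points.X[:, 0].round().astype(int)
    cc = points.X[:, 1].round().astype(int)
    out[rr, cc] = np.where(labels < 0, 0, labels + 1)
    return out


def save_label_image(path, image: np.ndarray) -> None:
    import tifffile

    tifffile.imwrite(str(path), image.astype(np.int32))


# ---------------------------------------------------------------------------
# heartbeat features


@dataclass
class HeartbeatFeatures:
    """Per-beat RR features; first and last beats are dropped because
    they lack a previous or next interval."""

    beat_times: np.ndarray  # interior beats only
    rr1: np.ndarray  # seconds to the previous beat
    rr2: np.ndarray  # seconds to the next beat

    def to_points(self) -> PointSet:
        return PointSet(np.c_[self.rr1, self.rr2])


def rr_features(beat_times) -> HeartbeatFeatures:
    """RR1/RR2 features from an increasing list of beat times (seconds)."""
    t = np.asarray(beat_times, dtype=float)
    if len(t) < 3:
        raise DataError("need at least 3 beats for RR features")
    if not (np.diff(t) > 0).all():
        bad = int(np.argwhere(np.diff(t) <= 0)[0, 0]) + 1
        raise DataError(f"beat times must be strictly increasing (violation at beat {bad})")
    rr = np.diff(t)
    return HeartbeatFeatures(beat_times=t[1:-1], rr1=rr[:-1], rr2=rr[1:])


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Fully serializable description of one clustering run."""

    metric: str = "euclidean"
    minkowski_p: float = 2.0
    topology: str = "auto"  # auto | full | knn
    k: int | None = None
    kernel: str = "gaussian"
    d_c: float | None = None
    neighbor_fraction: float = 0.02
    peak_mode: str = "top_n"  # top_n | threshold
    n_peaks: int | None = None
    tau_rho: float | None = None
    tau_delta: float | None = None
    cost: str = "minimax"  # minimax | cumulative | trained
    p: float = 1.0
    window: int = 4
    model_path: str | None = None
    noise: str | float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
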