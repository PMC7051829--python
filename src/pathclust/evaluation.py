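"""Pair-counting evaluation of a predicted labeling against ground truth.

All unordered point pairs are classified by co-membership: TP pairs are
co-clustered in both labelings, FP only in the prediction, FN only in
the truth, TN in neither.  The scores are

    Precision = TP / (TP + FP)        Recall = TP / (TP + FN)
    F1 = 2 * Precision * Recall / (Precision + Recall)
    J  = TP / (TP + FN + FP)

Noise points (label -1) are treated as singleton clusters -- each noise
point pairs with nothing -- so correctly rejecting background is
rewarded rather than ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DataError

logger = logging.getLogger(__name__)


@dataclass
class ContingencyCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total_pairs(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


def _noise_to_singletons(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=np.int64).copy()
    noise = labels == -1
    if noise.any():
        base = labels.max() + 1 if len(labels) else 0
        labels[noise] = base + np.arange(int(noise.sum()))
    return labels


def pairwise_contingency(pred, truth) -> ContingencyCounts:
    """TP/FP/FN/TN over unordered point pairs."""
    from sklearn.metrics.cluster import pair_confusion_matrix

    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if len(pred) != len(truth):
        raise DataError(f"label vectors differ in length: {len(pred)} vs {len(truth)}")
    p = _noise_to_singletons(pred)
    t = _noise_to_singletons(truth)
    # pair_confusion_matrix counts ordered pairs; halve for unordered.
    C = pair_confusion_matrix(t, p)
    return ContingencyCounts(
        TP=int(C[1, 1] // 2), FP=int(C[0, 1] // 2),
        FN=int(C[1, 0] // 2), TN=int(C[0, 0] // 2),
    )


def precision(counts: ContingencyCounts) -> float:
    if counts.TP + counts.FP == 0:
        logger.info("precision undefined (TP+FP=0); reporting 0")
        return 0.0
    return counts.TP / (counts.TP + counts.FP)


def recall(counts: ContingencyCounts) -> float:
    if counts.TP + counts.FN == 0:
        logger.info("recall undefined (TP+FN=0); reporting 0")
        return 0.0
    return counts.TP / (counts.TP + counts.FN)


def f1_score(counts: ContingencyCounts) -> float:
    p, r = precision(counts), recall(counts)
    if p + r == 0:
        return 0.0
    return 2 * p * r / (p + r)


def jaccard_index(counts: ContingencyCounts) -> float:
    denom = counts.TP + counts.FN + counts.FP
    if denom == 0:
        logger.info("Jaccard undefined (TP+FN+FP=0); reporting 0")
        return 0.0
    return counts.TP / denom


def report(pred, truth) -> dict:
    """Full evaluation report as a plain dict (JSON-friendly)."""
    c = pairwise_contingency(pred, truth)
    return {
        "TP": c.TP, "FP": c.FP, "FN": c.FN, "TN": c.TN,
        "precision": precision(c), "recall": recall(c),
        "F1": f1_score(c), "Jaccard": jaccard_index(c),
    }
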