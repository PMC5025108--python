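"""Pixel-level scoring of a predicted mask against ground truth.

Four metrics from the TP/TN/FP/FN confusion tallies:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    sensitivity = TP / (TP + FN)      (true-positive rate; under-segmentation)
    specificity = TN / (TN + FP)      (debris rejection)
    precision   = TP / (TP + FP)      (positive predictive value)

Batches report the unweighted per-image mean (the headline aggregate) and,
for transparency, the metrics of the pooled pixel counts — the two differ
whenever images have unequal foreground fractions.  A metric with a zero
denominator is reported as NaN, never silently as 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["ConfusionCounts", "confusion", "metrics", "evaluate_batch", "METRIC_NAMES"]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion(predicted: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally TP/TN/FP/FN pixels between two same-shape {0, 1} masks."""
    predicted = np.asarray(predicted).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if predicted.shape != truth.shape:
        raise ValueError(f"shape mismatch: {predicted.shape} vs {truth.shape}")
    tp = int(np.count_nonzero(predicted & truth))
    tn = int(np.count_nonzero(~predicted & ~truth))
    fp = int(np.count_nonzero(predicted & ~truth))
    fn = int(np.count_nonzero(~predicted & truth))
    return ConfusionCounts(tp, tn, fp, fn)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reporting NaN")
        return math.nan
    return num / den


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, sensitivity, specificity and precision from the tallies."""
    if counts.total == 0:
        raise ValueError("cannot score an empty confusion table")
    return {
        "accuracy": (counts.tp + counts.tn) / counts.total,
        "sensitivity": _ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        "specificity": _ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        "precision": _ratio(counts.tp, counts.tp + counts.fp, "precision"),
    }


def evaluate_batch(pairs: list[tuple[np.ndarray, np.ndarray]]) -> dict:
    """Score a batch of (predicted, truth) mask pairs.

    Returns ``{"per_image": [...], "mean": {...}, "pooled": {...}}`` where
    each per-image entry carries the four metrics plus raw counts, ``mean``
    is their unweighted average (NaN-aware) and ``pooled`` scores the
    summed pixel counts.
    """
    if not pairs:
        raise ValueError("need at least one (predicted, truth) pair")
    per_image = []
    pooled = ConfusionCounts(0, 0, 0, 0)
    for predicted, truth in pairs:
        counts = confusion(predicted, truth)
        pooled = pooled + counts
        entry = metrics(counts)
        entry.update(tp=counts.tp, tn=counts.tn, fp=counts.fp, fn=counts.fn)
        per_image.append(entry)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = {
            name: float(np.nanmean([e[name] for e in per_image]))
            for name in METRIC_NAMES
        }
    return {"per_image": per_image, "mean": mean, "pooled": metrics(pooled)}
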