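"""Evaluation metrics for detection and classification.

Because animal detections thin out with altitude, raw accuracy is dominated
by the non-animal class at far range; the balanced classification accuracy —
the mean of sensitivity (true positive rate) and specificity (true negative
rate) — corrects for that imbalance and is the headline measure. Detection
is scored separately as the ratio of algorithm detections to manually (or
synthetically) known true objects. The inverse-square pixel-footprint model
links altitude to the number of pixels an object of fixed ground area
occupies, which drives the altitude degradation of both scores.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "ConfusionMatrix",
    "MetricsReport",
    "confusion_metrics",
    "detection_performance",
    "pixel_footprint",
    "evaluate_range",
]


@dataclass
class ConfusionMatrix:
    """TP/FP/FN/TN counts with animal as the positive class."""

    TP: int
    FP: int
    FN: int
    TN: int

    def __post_init__(self) -> None:
        for name in ("TP", "FP", "FN", "TN"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN

    @classmethod
    def from_records(
        cls, true: Sequence[str], pred: Sequence[str], positive: str = "animal"
    ) -> "ConfusionMatrix":
        t = np.asarray(true)
        p = np.asarray(pred)
        if t.shape != p.shape:
            raise ValueError("true and pred lengths differ")
        pos_t = t == positive
        pos_p = p == positive
        return cls(
            TP=int(np.sum(pos_t & pos_p)),
            FP=int(np.sum(~pos_t & pos_p)),
            FN=int(np.sum(pos_t & ~pos_p)),
            TN=int(np.sum(~pos_t & ~pos_p)),
        )


@dataclass
class MetricsReport:
    accuracy: float
    balanced_accuracy: float
    sensitivity: float
    specificity: float

    def to_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 4),
            "balanced_accuracy": round(self.balanced_accuracy, 4),
            "sensitivity": round(self.sensitivity, 4),
            "specificity": round(self.specificity, 4),
        }

    def __str__(self) -> str:
        d = self.to_dict()
        width = max(len(k) for k in d)
        return "\n".join(f"{k:<{width}}  {v:.3f}" for k, v in d.items())


def confusion_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """Accuracy, balanced accuracy, sensitivity and specificity.

    Sensitivity = TP/(TP+FN); specificity = TN/(FP+TN); balanced accuracy is
    their mean. Raises when either margin is empty.
    """
    if cm.TP + cm.FN == 0:
        raise ValueError("no positive-class records (TP+FN = 0)")
    if cm.FP + cm.TN == 0:
        raise ValueError("no negative-class records (FP+TN = 0)")
    sens = cm.TP / (cm.TP + cm.FN)
    spec = cm.TN / (cm.FP + cm.TN)
    return MetricsReport(
        accuracy=(cm.TP + cm.TN) / cm.total,
        balanced_accuracy=(sens + spec) / 2.0,
        sensitivity=sens,
        specificity=spec,
    )


def detection_performance(n_detected: int, n_actual: int) -> float:
    """Ratio of detected objects to true objects."""
    if n_actual <= 0:
        raise ValueError("n_actual must be positive")
    return n_detected / n_actual


def pixel_footprint(pixels_ref: float, alt_ref: float, alt: float) -> int:
    """Pixels an object covers at ``alt``, from a reference measurement.

    The ground sample distance grows linearly with altitude, so the pixel
    count falls with the altitude squared: round(pixels_ref * (alt_ref/alt)^2).
    """
    if alt_ref <= 0 or alt <= 0:
        raise ValueError("altitudes must be positive")
    return int(round(pixels_ref * (alt_ref / alt) ** 2))


def evaluate_range(
    records: Iterable[tuple[float, str, str]],
    ranges: Sequence[tuple[float, float]] = ((3.0, 10.0), (10.0, 20.0)),
) -> dict[tuple[float, float], MetricsReport]:
    """Per-altitude-band metrics from (altitude, true, predicted) records.

    Bands are half-open ``[low, high)``, so a record at exactly 10 m falls
    in the 10–20 m band only. Bands with an empty class margin are omitted
    with a warning.
    """
    records = list(records)
    if not records:
        raise ValueError("no records")
    out: dict[tuple[float, float], MetricsReport] = {}
    for low, high in ranges:
        sel = [(t, p) for alt, t, p in records if low <= alt < high]
        if not sel:
            warnings.warn(f"altitude range [{low}, {high}) has no records")
            continue
        cm = ConfusionMatrix.from_records([t for t, _ in sel], [p for _, p in sel])
        try:
            out[(low, high)] = confusion_metrics(cm)
        except ValueError as err:
            warnings.warn(f"altitude range [{low}, {high}) skipped: {err}")
    return out
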