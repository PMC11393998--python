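"""Evaluation metrics: OKS / AP / mAP for keypoints, MAE / MRE for
measurements.

Object Keypoint Similarity between a prediction and an annotation of the
same animal:

    OKS = sum_i exp(-d_i^2 / (2 S^2 sigma_i^2)) * [v_i > 0]
          / sum_i [v_i > 0]

where d_i is the pixel distance for landmark i, S the object scale
(sqrt of the body bounding-box area), sigma_i the per-landmark
normalization factor and v_i the *annotation* visibility (1 and 2 both
count as marked).  A detection with OKS strictly greater than the
threshold (default 0.5) is a true positive; AP is the true-positive
fraction at that single threshold and mAP the mean AP over categories.

Measurement accuracy against manual ground truth uses mean absolute error
MAE = (1/n) sum |x_hat - x| (same units as the input) and mean relative
error MRE = (100/n) sum |x_hat - x| / x, in percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Sequence, Tuple

import numpy as np

from .errors import UndefinedMetricError, ValidationError
from .keypoints import LANDMARKS, KeypointSet

__all__ = [
    "OksParams",
    "PairedMeasurements",
    "oks",
    "average_precision",
    "mean_ap",
    "precision_recall",
    "mae",
    "mre",
    "max_relative_error",
]

#: Uniform default normalization factor; cattle-specific per-landmark
#: values are not established, so a mid-range pose-estimation sigma is
#: applied to every landmark (override per landmark via OksParams).
DEFAULT_SIGMA = 0.05


@dataclass
class OksParams:
    """Per-landmark sigmas and the object scale S (pixels)."""

    scale: float
    sigmas: Dict[str, float] = field(
        default_factory=lambda: {name: DEFAULT_SIGMA for name in LANDMARKS})

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValidationError(f"object scale must be > 0, got {self.scale}")
        bad = {n: s for n, s in self.sigmas.items() if not s > 0}
        if bad:
            raise ValidationError(f"non-positive sigmas: {bad}")

    @classmethod
    def from_bbox(cls, bbox: Sequence[float],
                  sigmas: Dict[str, float] | None = None) -> "OksParams":
        """Scale from a COCO-style [x, y, w, h] box: S = sqrt(w * h)."""
        w, h = float(bbox[2]), float(bbox[3])
        p = cls(scale=math.sqrt(w * h))
        if sigmas:
            p.sigmas.update(sigmas)
        return p


@dataclass
class PairedMeasurements:
    """Manual (x) and automatic (x_hat) values for the same animals."""

    manual: np.ndarray
    automatic: np.ndarray
    ids: Tuple = ()

    def __post_init__(self) -> None:
        self.manual = np.asarray(self.manual, dtype=float)
        self.automatic = np.asarray(self.automatic, dtype=float)
        if self.manual.shape != self.automatic.shape:
            raise ValidationError(
                f"length mismatch: {self.manual.shape} vs {self.automatic.shape}")
        if self.manual.size < 1:
            raise ValidationError("need at least one measurement pair")


def oks(pred: KeypointSet, truth: KeypointSet, p: OksParams) -> float:
    """Object Keypoint Similarity in [0, 1]; see module docstring."""
    num = 0.0
    den = 0
    for name in LANDMARKS:
        t = truth.get(name)
        if t is None or t.visibility <= 0:
            continue
        sigma = p.sigmas.get(name, DEFAULT_SIGMA)
        pr = pred.get(name)
        if pr is None:
            # an unpredicted marked landmark contributes zero similarity
            den += 1
            continue
        d2 = (pr.u - t.u) ** 2 + (pr.v - t.v) ** 2
        num += math.exp(-d2 / (2.0 * p.scale ** 2 * sigma ** 2))
        den += 1
    if den == 0:
        raise UndefinedMetricError("OKS undefined: no marked truth landmark")
    return num / den


def average_precision(oks_values: Sequence[float], threshold: float = 0.5) -> float:
    """Fraction of detections whose OKS strictly exceeds ``threshold``.

    An OKS less than or equal to the threshold counts as a false positive.
    """
    vals = np.asarray(list(oks_values), dtype=float)
    if vals.size == 0:
        raise UndefinedMetricError("AP undefined on an empty OKS list")
    return float(np.mean(vals > threshold))


def mean_ap(per_class_ap: Sequence[float]) -> float:
    """Arithmetic mean of per-category AP values."""
    vals = np.asarray(list(per_class_ap), dtype=float)
    if vals.size == 0:
        raise UndefinedMetricError("mAP undefined on an empty AP list")
    return float(vals.mean())


def precision_recall(tp: int, fp: int, fn: int) -> Tuple[float, float]:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN)."""
    if min(tp, fp, fn) < 0:
        raise ValidationError("counts must be non-negative")
    if tp + fp == 0:
        raise UndefinedMetricError("precision undefined: TP + FP = 0")
    if tp + fn == 0:
        raise UndefinedMetricError("recall undefined: TP + FN = 0")
    return tp / (tp + fp), tp / (tp + fn)


def mae(pm: PairedMeasurements) -> float:
    """Mean absolute error, in the input units."""
    return float(np.mean(np.abs(pm.automatic - pm.manual)))


def mre(pm: PairedMeasurements) -> float:
    """Mean relative error in percent of the manual value."""
    if np.any(pm.manual <= 0):
        raise ValidationError("MRE requires all manual values > 0")
    return float(100.0 * np.mean(np.abs(pm.automatic - pm.manual) / pm.manual))


def max_relative_error(pm: PairedMeasurements) -> float:
    """Largest single relative error in percent of the manual value."""
    if np.any(pm.manual <= 0):
        raise ValidationError("relative error requires all manual values > 0")
    return float(100.0 * np.max(np.abs(pm.automatic - pm.manual) / pm.manual))
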