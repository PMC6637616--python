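"""Localization evaluation: IOU, threshold accuracies, coverage, and the
weak center-distance criterion.

Accuracy at an IOU threshold ``t`` is the percentage of image pairs with
``IOU > t`` (strict).  Because prose reports of "average overlap" are
ambiguous between IOU and the asymmetric coverage fraction
``area(pred and gt) / area(gt)``, the report carries both.  The
center-distance criterion (prediction correct when the centers are closer
than the expected disc diameter, i.e. whenever IOU > 0) is included as the
much weaker bar some of the localization literature uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .types import BoundingBox

__all__ = [
    "LocalizationReport",
    "iou",
    "coverage_fraction",
    "center_criterion",
    "evaluate",
    "DEFAULT_THRESHOLDS",
]

logger = logging.getLogger(__name__)

#: the standard reporting grid for threshold accuracies
DEFAULT_THRESHOLDS = (0.2, 0.5, 0.6, 0.7, 0.8)


def _intersection_area(a: BoundingBox, b: BoundingBox) -> int:
    iw = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    ih = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if iw <= 0 or ih <= 0:
        return 0
    return iw * ih


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes; symmetric, in [0, 1]."""
    inter = _intersection_area(a, b)
    union = a.area + b.area - inter
    return inter / union


def coverage_fraction(pred: BoundingBox, gt: BoundingBox) -> float:
    """Fraction of the ground-truth area the prediction covers (asymmetric)."""
    return _intersection_area(pred, gt) / gt.area


def center_criterion(pred: BoundingBox, gt: BoundingBox) -> bool:
    """True iff the center distance is strictly below the expected disc
    diameter, taken as ``max(gt width, gt height)`` — equivalent to IOU > 0
    for equal-sized boxes."""
    (px, py), (gx, gy) = pred.center, gt.center
    dist = ((px - gx) ** 2 + (py - gy) ** 2) ** 0.5
    return dist < max(gt.width, gt.height)


@dataclass
class PerImageEval:
    image_id: str
    iou: float
    coverage_frac: float
    center_ok: bool
    correct_at: dict[float, bool]


@dataclass
class LocalizationReport:
    """Aggregate localization quality over a prediction/ground-truth set."""

    per_image: list[PerImageEval]
    accuracy_at: dict[float, float]  # threshold -> percent
    mean_iou: float  # percent
    mean_coverage: float  # percent
    center_accuracy: float  # percent
    n: int = field(default=0)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "accuracy_at": {str(t): v for t, v in self.accuracy_at.items()},
            "mean_iou": self.mean_iou,
            "mean_coverage": self.mean_coverage,
            "center_accuracy": self.center_accuracy,
            "per_image": [
                {
                    "image_id": p.image_id,
                    "iou": p.iou,
                    "coverage_frac": p.coverage_frac,
                    "center_ok": p.center_ok,
                    "correct_at": {str(t): bool(v) for t, v in p.correct_at.items()},
                }
                for p in self.per_image
            ],
        }


def evaluate(
    preds: dict[str, BoundingBox],
    gts: dict[str, BoundingBox],
    thresholds=DEFAULT_THRESHOLDS,
) -> LocalizationReport:
    """Score predictions against ground truth over every GT image.

    A ground-truth image without a prediction counts as incorrect at every
    threshold (IOU and coverage 0) and is logged.  ``accuracy_at[t] = 100 *
    #(IOU > t) / n`` with strict inequality.
    """
    if not gts:
        raise ValueError("empty ground-truth set")
    thresholds = tuple(thresholds)
    per_image: list[PerImageEval] = []
    for image_id in sorted(gts):
        gt = gts[image_id]
        pred = preds.get(image_id)
        if pred is None:
            logger.warning("no prediction for image %r; counted incorrect", image_id)
            per_image.append(PerImageEval(
                image_id, 0.0, 0.0, False, {t: False for t in thresholds}
            ))
            continue
        v = iou(pred, gt)
        per_image.append(PerImageEval(
            image_id, v, coverage_fraction(pred, gt), center_criterion(pred, gt),
            {t: v > t for t in thresholds},
        ))
    n = len(per_image)
    accuracy_at = {
        t: 100.0 * sum(p.correct_at[t] for p in per_image) / n for t in thresholds
    }
    return LocalizationReport(
        per_image=per_image,
        accuracy_at=accuracy_at,
        mean_iou=100.0 * sum(p.iou for p in per_image) / n,
        mean_coverage=100.0 * sum(p.coverage_frac for p in per_image) / n,
        center_accuracy=100.0 * sum(p.center_ok for p in per_image) / n,
        n=n,
    )
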