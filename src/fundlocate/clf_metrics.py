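"""Classification evaluation: confusion counts, precision / recall / F1 /
specificity, ROC-AUC, sensitivity at a target specificity, and k-fold splits.

Definitions (per class c, counts on raw label/prediction lists):

* precision = 100 * TP / (TP + FP)
* recall (sensitivity) = 100 * TP / (TP + FN)
* F1 = harmonic mean of precision and recall, reported on the [0, 1] scale
* specificity (true-negative rate) = 100 * TN / (TN + FP)

For a binary problem the specificity of one class equals the recall of the
other (complementarity).  Report totals are support-weighted means of the
per-class precision and F1; the "recall" slot of the total row is the
overall accuracy, as class-imbalanced screening studies conventionally
tabulate it.  Undefined metrics (zero denominator) raise
:class:`UndefinedMetricError` instead of silently returning 0 — except
F1 at precision = recall = 0, which is 0 by convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ConfusionCounts",
    "ClassMetrics",
    "ClassificationReport",
    "ROCCurve",
    "FoldSplit",
    "UndefinedMetricError",
    "confusion",
    "precision",
    "recall",
    "f1",
    "specificity",
    "report",
    "roc_auc",
    "sensitivity_at_specificity",
    "kfold_split",
    "stratified_kfold_split",
    "CLASSES",
]

CLASSES = ("healthy", "glaucoma")


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero; the quantity is undefined."""


@dataclass
class ConfusionCounts:
    """Per-class TP/FP/FN/TN over a prediction run."""

    counts: dict[str, dict[str, int]]
    n: int

    def __getitem__(self, cls: str) -> dict[str, int]:
        return self.counts[cls]

    def support(self, cls: str) -> int:
        return self.counts[cls]["tp"] + self.counts[cls]["fn"]


@dataclass
class ClassMetrics:
    precision: float  # percent
    recall: float  # percent
    f1: float  # ratio in [0, 1]
    support: int


@dataclass
class ClassificationReport:
    per_class: dict[str, ClassMetrics]
    total_precision: float  # percent, support-weighted
    accuracy: float  # percent
    total_f1: float  # ratio, support-weighted
    n: int

    def to_dict(self) -> dict:
        return {
            "per_class": {
                c: vars(m).copy() for c, m in self.per_class.items()
            },
            "total_precision": self.total_precision,
            "accuracy": self.accuracy,
            "total_f1": self.total_f1,
            "n": self.n,
        }


@dataclass
class ROCCurve:
    """ROC curve as (specificity, sensitivity) points over score thresholds,
    plus the trapezoidal AUC (equal to pair-concordance probability with
    half-credit for ties)."""

    points: list[tuple[float, float]]  # (specificity, sensitivity), percent
    thresholds: list[float]
    auc: float


@dataclass
class FoldSplit:
    k: int
    assignment: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignment.items() if f == fold]


def _validate_lists(labels, preds) -> None:
    if len(labels) != len(preds):
        raise ValueError(f"length mismatch: {len(labels)} labels vs {len(preds)} predictions")
    if len(labels) == 0:
        raise ValueError("empty label list")
    bad = set(labels) | set(preds)
    if not bad <= set(CLASSES):
        raise ValueError(f"unknown classes {sorted(bad - set(CLASSES))}; expected {CLASSES}")


def confusion(labels: list[str], preds: list[str]) -> ConfusionCounts:
    """Per-class confusion counts from parallel label/prediction lists."""
    _validate_lists(labels, preds)
    counts = {}
    for cls in CLASSES:
        tp = sum(1 for l, p in zip(labels, preds) if l == cls and p == cls)
        fp = sum(1 for l, p in zip(labels, preds) if l != cls and p == cls)
        fn = sum(1 for l, p in zip(labels, preds) if l == cls and p != cls)
        tn = sum(1 for l, p in zip(labels, preds) if l != cls and p != cls)
        counts[cls] = {"tp": tp, "fp": fp, "fn": fn, "tn": tn}
    return ConfusionCounts(counts=counts, n=len(labels))


def precision(counts: ConfusionCounts, cls: str) -> float:
    c = counts[cls]
    denom = c["tp"] + c["fp"]
    if denom == 0:
        raise UndefinedMetricError(f"precision undefined for {cls!r}: no predictions of that class")
    return 100.0 * c["tp"] / denom


def recall(counts: ConfusionCounts, cls: str) -> float:
    c = counts[cls]
    denom = c["tp"] + c["fn"]
    if denom == 0:
        raise UndefinedMetricError(f"recall undefined for {cls!r}: zero support")
    return 100.0 * c["tp"] / denom


def f1(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall (percent in, ratio out).

    Returns 0 when both are 0 (documented convention)."""
    if precision_pct == 0 and recall_pct == 0:
        return 0.0
    return 2.0 * precision_pct * recall_pct / (precision_pct + recall_pct) / 100.0


def specificity(counts: ConfusionCounts, cls: str) -> float:
    c = counts[cls]
    denom = c["tn"] + c["fp"]
    if denom == 0:
        raise UndefinedMetricError(f"specificity undefined for {cls!r}: no negatives")
    return 100.0 * c["tn"] / denom


def report(labels: list[str], preds: list[str]) -> ClassificationReport:
    """Per-class metrics, support-weighted totals and overall accuracy."""
    counts = confusion(labels, preds)
    per_class: dict[str, ClassMetrics] = {}
    for cls in CLASSES:
        p = precision(counts, cls)
        r = recall(counts, cls)
        per_class[cls] = ClassMetrics(
            precision=p, recall=r, f1=f1(p, r), support=counts.support(cls)
        )
    n = counts.n
    total_precision = sum(m.precision * m.support for m in per_class.values()) / n
    total_f1 = sum(m.f1 * m.support for m in per_class.values()) / n
    accuracy = 100.0 * sum(1 for l, p in zip(labels, preds) if l == p) / n
    return ClassificationReport(
        per_class=per_class,
        total_precision=total_precision,
        accuracy=accuracy,
        total_f1=total_f1,
        n=n,
    )


def roc_auc(scores, labels, positive: str = "glaucoma") -> ROCCurve:
    """ROC curve and trapezoidal AUC from per-image positive-class scores.

    A point is computed at every distinct score threshold (predict positive
    when ``score >= t``); the trapezoid over sensitivity vs
    ``1 - specificity`` equals the concordance probability
    ``P(score_pos > score_neg) + 0.5 P(tie)``.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray([1 if l == positive else 0 for l in labels])
    if len(scores) != len(y):
        raise ValueError("length mismatch between scores and labels")
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    y_sorted = y[order]
    # cumulative counts at each distinct-threshold boundary
    distinct = np.nonzero(np.diff(s_sorted))[0]
    idx = np.concatenate([distinct, [len(s_sorted) - 1]])
    tps = np.cumsum(y_sorted)[idx]
    fps = np.cumsum(1 - y_sorted)[idx]
    tpr = np.concatenate([[0.0], tps / n_pos])
    fpr = np.concatenate([[0.0], fps / n_neg])
    thresholds = np.concatenate([[np.inf], s_sorted[idx]])
    auc = float(np.trapezoid(tpr, fpr))
    points = [(100.0 * (1.0 - f), 100.0 * t) for f, t in zip(fpr, tpr)]
    return ROCCurve(points=points, thresholds=[float(t) for t in thresholds], auc=auc)


def sensitivity_at_specificity(curve: ROCCurve, target: float) -> float:
    """Sensitivity (%) at the last ROC step whose specificity is still >= the
    target (%), without interpolation.

    This is the conservative step convention: the reported sensitivity is
    attainable at an operating point that actually meets the specificity
    requirement.
    """
    if not (0 < target <= 100):
        raise ValueError(f"target specificity must be in (0, 100], got {target}")
    eligible = [sens for spec, sens in curve.points if spec >= target]
    if not eligible:
        return 0.0
    return max(eligible)


def kfold_split(ids: list[str], k: int, seed: int = 0) -> FoldSplit:
    """Random partition of ids into k folds whose sizes differ by at most 1."""
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds number of ids ({len(ids)})")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate ids")
    rng = np.random.default_rng(seed)
    shuffled = list(ids)
    rng.shuffle(shuffled)
    return FoldSplit(k=k, assignment={i: idx % k for idx, i in enumerate(shuffled)})


def stratified_kfold_split(
    ids: list[str], labels: list[str], k: int, seed: int = 0
) -> FoldSplit:
    """k folds preserving the class proportions (round-robin within class)."""
    if len(ids) != len(labels):
        raise ValueError("length mismatch between ids and labels")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    if k > len(ids):
        raise ValueError(f"k = {k} exceeds number of ids ({len(ids)})")
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    offset = 0
    for cls in sorted(set(labels)):
        cls_ids = [i for i, l in zip(ids, labels) if l == cls]
        rng.shuffle(cls_ids)
        for j, i in enumerate(cls_ids):
            assignment[i] = (j + offset) % k
        offset += len(cls_ids)
    return FoldSplit(k=k, assignment=assignment)
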