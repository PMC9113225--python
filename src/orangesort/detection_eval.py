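"""Detection post-processing (NMS) and single-class detection metrics.

Precision = TP/(TP+FP), Recall = TP/GroundTruth, F1 = 2PR/(P+R); a
detection is a true positive when it matches an unclaimed ground-truth
box at IoU >= 0.5 (greedy, in descending confidence). Average precision
is the area under the precision-recall curve obtained by sweeping the
confidence threshold, integrated exactly over the empirical step curve
(no precision-envelope smoothing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BoundingBox, Detection, iou

__all__ = [
    "MatchOutcome",
    "PRCurve",
    "nms",
    "match_detections",
    "precision_recall_f1",
    "average_precision",
    "pr_curve",
]


@dataclass(frozen=True)
class MatchOutcome:
    """TP/FP tallies against a set of manually marked targets."""

    tp: int
    fp: int
    ground_truth: int

    def __post_init__(self) -> None:
        if self.tp < 0 or self.fp < 0:
            raise ValueError("tp and fp must be non-negative")
        if self.tp > self.ground_truth:
            raise ValueError("tp cannot exceed the number of ground-truth targets")


@dataclass(frozen=True)
class PRCurve:
    """Ordered (recall, precision) points; recall is nondecreasing."""

    recall: tuple[float, ...]
    precision: tuple[float, ...]


def nms(
    detections: list[Detection],
    iou_threshold: float = 0.5,
    score_threshold: float = 0.25,
) -> list[Detection]:
    """Greedy non-maximum suppression.

    Drops detections below ``score_threshold``, then walks the rest in
    descending confidence, keeping a box only if its IoU with every
    already-kept box is below ``iou_threshold``. Output is sorted by
    confidence, ties broken by input order.
    """
    order = sorted(
        (d for d in detections if d.confidence >= score_threshold),
        key=lambda d: -d.confidence,
    )
    kept: list[Detection] = []
    for d in order:
        if all(iou(d.box, k.box) < iou_threshold for k in kept):
            kept.append(d)
    return kept


def match_detections(
    dets: list[Detection],
    gts: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> MatchOutcome:
    """Greedy one-to-one matching of detections to ground truth.

    In descending confidence, a detection claiming an unclaimed
    ground-truth box at IoU >= threshold is a TP; everything else is an
    FP. Each ground-truth box can be claimed once.
    """
    claimed = [False] * len(gts)
    tp = fp = 0
    for d in sorted(dets, key=lambda d: -d.confidence):
        best, best_iou = -1, iou_threshold
        for gi, g in enumerate(gts):
            if claimed[gi]:
                continue
            v = iou(d.box, g)
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            claimed[best] = True
            tp += 1
        else:
            fp += 1
    return MatchOutcome(tp, fp, len(gts))


def precision_recall_f1(m: MatchOutcome) -> tuple[float | None, float | None, float | None]:
    """Precision, recall and F1-score from a match outcome.

    Undefined quantities (zero denominators) are returned as ``None``
    rather than coerced to zero.
    """
    precision = m.tp / (m.tp + m.fp) if (m.tp + m.fp) > 0 else None
    recall = m.tp / m.ground_truth if m.ground_truth > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1


def _matched_labels(
    scored: list[Detection],
    gts: list[BoundingBox],
    iou_threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-detection TP labels in descending-confidence order."""
    order = sorted(range(len(scored)), key=lambda i: -scored[i].confidence)
    claimed = [False] * len(gts)
    labels = np.zeros(len(scored), dtype=bool)
    confs = np.zeros(len(scored))
    for rank, i in enumerate(order):
        d = scored[i]
        confs[rank] = d.confidence
        best, best_iou = -1, iou_threshold
        for gi, g in enumerate(gts):
            if claimed[gi]:
                continue
            v = iou(d.box, g)
            if v >= best_iou:
                best, best_iou = gi, v
        if best >= 0:
            claimed[best] = True
            labels[rank] = True
    return labels, confs


def pr_curve(
    scored: list[Detection],
    gts: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> PRCurve:
    """Precision-recall curve from sweeping the confidence threshold."""
    if len(gts) == 0:
        raise ValueError("need at least one ground-truth box")
    labels, _ = _matched_labels(scored, gts, iou_threshold)
    tp = np.cumsum(labels)
    fp = np.cumsum(~labels)
    recall = tp / len(gts)
    precision = tp / (tp + fp)
    return PRCurve(tuple(recall.tolist()), tuple(precision.tolist()))


def average_precision(
    scored: list[Detection],
    gts: list[BoundingBox],
    iou_threshold: float = 0.5,
) -> float:
    """Area under the empirical precision-recall curve.

    AP = sum over curve points of (R_k - R_{k-1}) * P_k, the exact
    integral of the step curve; invariant under any strictly monotone
    rescaling of the confidences.
    """
    curve = pr_curve(scored, gts, iou_threshold)
    r = np.asarray(curve.recall)
    p = np.asarray(curve.precision)
    dr = np.diff(np.concatenate([[0.0], r]))
    return float(np.sum(dr * p))
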