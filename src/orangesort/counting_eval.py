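"""Counting-accuracy metrics and track-level audit against ground truth.

The counting error of one sequence is the relative count deviation
|automated - manual| / manual; across sequences the mean absolute error
(MAE) and the population standard deviation summarize accuracy. A
predicted track list is audited against ground-truth tracks by majority
frame overlap, splitting counted identities into correct counts,
double-counting instances (extra identities on an already-claimed
fruit) and false counts (identities matching no fruit).
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .core import BoundingBox, iou

__all__ = [
    "CountReport",
    "counting_error",
    "mae",
    "sd",
    "categorize_counts",
    "id_switches",
]


@dataclass(frozen=True)
class CountReport:
    """Categorized counting result for one sequence."""

    n_counted: int
    n_correct: int
    n_false: int
    n_double: int
    counting_error: float | None = None

    def __post_init__(self) -> None:
        if self.n_counted != self.n_correct + self.n_false + self.n_double:
            raise ValueError("n_correct + n_false + n_double must equal n_counted")


def counting_error(pred_count: int, manual_count: int) -> float:
    """Relative counting error |pred - manual| / manual of one sequence."""
    if manual_count <= 0:
        raise ValueError(f"manual count must be positive, got {manual_count}")
    return abs(pred_count - manual_count) / manual_count


def mae(errors: list[float]) -> float:
    """Mean absolute error over per-sequence counting errors."""
    if len(errors) == 0:
        raise ValueError("empty error series")
    return float(np.mean(errors))


def sd(errors: list[float]) -> float:
    """Population standard deviation (divide by m) of per-sequence errors."""
    if len(errors) == 0:
        raise ValueError("empty error series")
    return float(np.std(errors))


TrackBoxes = dict[int, dict[int, BoundingBox]]
"""Track id -> {frame index -> box}."""


def categorize_counts(
    pred_tracks: TrackBoxes,
    gt_tracks: TrackBoxes,
    iou_match_threshold: float = 0.5,
) -> CountReport:
    """Audit predicted track identities against ground-truth fruits.

    Each predicted track is assigned to the ground-truth fruit with
    which it shares the most frames at IoU >= threshold (no fruit at
    any frame -> unassigned). Per fruit, the earliest-born assigned
    track is a correct count, further tracks are double-counting
    instances; unassigned tracks are false counts. The three categories
    partition the counted tracks.
    """
    assignment: dict[int, int | None] = {}
    for tid, frames in pred_tracks.items():
        overlap: dict[int, int] = defaultdict(int)
        for fidx, box in frames.items():
            for gid, gframes in gt_tracks.items():
                gbox = gframes.get(fidx)
                if gbox is not None and iou(box, gbox) >= iou_match_threshold:
                    overlap[gid] += 1
        assignment[tid] = max(overlap, key=lambda g: (overlap[g], -g)) if overlap else None

    claimed: set[int] = set()
    n_correct = n_double = n_false = 0
    # birth order = first frame, then id (ids increase with creation)
    for tid in sorted(pred_tracks, key=lambda t: (min(pred_tracks[t]), t)):
        gid = assignment[tid]
        if gid is None:
            n_false += 1
        elif gid in claimed:
            n_double += 1
        else:
            claimed.add(gid)
            n_correct += 1
    return CountReport(len(pred_tracks), n_correct, n_false, n_double)


def id_switches(pred_tracks: TrackBoxes, gt_tracks: TrackBoxes, iou_match_threshold: float = 0.5) -> int:
    """Count identity fragmentation via ground-truth correspondence.

    For each fruit, the number of distinct predicted identities assigned
    to it (by majority frame overlap) minus one, summed over fruits: 0
    means every fruit kept a single identity throughout.
    """
    per_fruit: dict[int, set[int]] = defaultdict(set)
    for tid, frames in pred_tracks.items():
        overlap: dict[int, int] = defaultdict(int)
        for fidx, box in frames.items():
            for gid, gframes in gt_tracks.items():
                gbox = gframes.get(fidx)
                if gbox is not None and iou(box, gbox) >= iou_match_threshold:
                    overlap[gid] += 1
        if overlap:
            gid = max(overlap, key=lambda g: (overlap[g], -g))
            per_fruit[gid].add(tid)
    return sum(len(ids) - 1 for ids in per_fruit.values())
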