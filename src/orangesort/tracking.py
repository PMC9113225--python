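"""SORT-style tracking with motion-displacement estimation and region counting.

The tracker links per-frame detections into identity-labelled tracks
(tracking-by-detection). Each track carries a constant-velocity Kalman
filter over ``(cx, cy, s, r)`` — box center, area ``s = w*h`` and aspect
ratio ``r = w/h`` — the SORT parameterization. Frame by frame, predicted
track boxes are matched to detections with the Hungarian algorithm under
an IoU gate, splitting boxes into three categories: correctly matched
detections (Kalman update), unmatched detections (new tracks) and
unmatched tracks.

The orchard-specific extension handles the unmatched tracks. Fruits are
stationary and the camera translates uniformly, so every correctly
tracked target moves by (almost) the same image displacement between
consecutive frames. An unmatched track is therefore propagated by the
*mean displacement* (dx, dy) of the matched tracks, while its width and
height shrink by a scale-decay factor alpha per unobserved frame
(occlusion is gradual, so the visible pixel area of an occluded fruit
decreases). A track whose area falls below a fixed fraction of its
birth area is deemed fully occluded and deleted. Disabling displacement
estimation (``use_displacement=False``) recovers the plain SORT
baseline, where unmatched tracks coast on the Kalman prediction and die
after ``max_age`` unmatched frames.

Counting strategy: the fruit count is the number of track identities
with at least ``min_hits`` matched frames. Optionally the tracker is
restricted to a central band of the frame (``use_region``), the middle
3/5 of the frame width by default; fruits occluded near the entry or
exit edge are then never tracked there, which removes the dominant
double-counting states.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import BoundingBox, Detection, SequenceMeta, iou

__all__ = [
    "TrackerConfig",
    "Track",
    "AssociationResult",
    "DisplacementEstimate",
    "TrackOutput",
    "Tracker",
    "associate",
    "mean_displacement",
    "estimate_unmatched",
    "filter_region",
    "outputs_to_track_boxes",
    "run_sequence",
]


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class TrackerConfig:
    """Tunable tracker parameters.

    Parameters
    ----------
    iou_threshold : float
        Association gate; matches with IoU below it are broken.
    alpha : float
        Scale-decay factor in (0, 1): width and height of an unmatched
        track shrink to (w*alpha, h*alpha) per estimated frame.
    scale_delete_ratio : float
        A track is deleted once its current area w*h drops below
        ``scale_delete_ratio`` times its area at creation.
    min_hits : int
        Matched frames required before a track identity is counted as a
        fruit (suppresses one-frame false detections).
    region_lo, region_hi : float
        Counting-region bounds as fractions of the frame width; the
        defaults keep the central 3/5 of the frame.
    use_region : bool
        Pre-filter detections to the counting region.
    use_displacement : bool
        Propagate unmatched tracks by mean displacement with scale
        decay; ``False`` gives the plain SORT baseline.
    max_age : int
        (Baseline mode only) unmatched frames a coasting track survives.
    """

    iou_threshold: float = 0.3
    alpha: float = 0.95
    scale_delete_ratio: float = 0.25
    min_hits: int = 2
    region_lo: float = 0.2
    region_hi: float = 0.8
    use_region: bool = False
    use_displacement: bool = True
    max_age: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.region_lo < self.region_hi <= 1.0):
            raise ValueError("require 0 <= region_lo < region_hi <= 1")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if not (0.0 < self.scale_delete_ratio < 1.0):
            raise ValueError("scale_delete_ratio must lie in (0, 1)")


# --------------------------------------------------------------------------
# Kalman filter (SORT parameterization)
# --------------------------------------------------------------------------

def _box_to_z(box: BoundingBox) -> np.ndarray:
    return np.array([box.cx, box.cy, box.w * box.h, box.w / box.h], dtype=float)


def _z_to_box(z: np.ndarray) -> BoundingBox:
    cx, cy, s, r = z[:4]
    s = max(s, 1e-12)
    r = max(r, 1e-12)
    w = math.sqrt(s * r)
    return BoundingBox(cx, cy, w, s / w)


class KalmanBoxFilter:
    """Constant-velocity Kalman filter over (cx, cy, s, r, vcx, vcy, vs).

    Matrices follow the SORT defaults: aspect ratio has no velocity,
    high initial velocity uncertainty, damped process noise on the
    velocity block.
    """

    def __init__(self, box: BoundingBox) -> None:
        self.F = np.eye(7)
        self.F[0, 4] = self.F[1, 5] = self.F[2, 6] = 1.0
        self.H = np.zeros((4, 7))
        self.H[:4, :4] = np.eye(4)
        self.R = np.diag([1.0, 1.0, 10.0, 10.0])
        self.P = np.diag([10.0, 10.0, 10.0, 10.0, 1e4, 1e4, 1e4])
        self.Q = np.diag([1.0, 1.0, 1.0, 1.0, 0.01, 0.01, 1e-4])
        self.x = np.zeros(7)
        self.x[:4] = _box_to_z(box)

    def predict(self) -> BoundingBox:
        # keep area non-negative under a negative area velocity
        if self.x[2] + self.x[6] <= 0:
            self.x[6] = 0.0
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        if not np.all(np.isfinite(self.P)):
            raise FloatingPointError("Kalman covariance became non-finite")
        return _z_to_box(self.x)

    def update(self, box: BoundingBox) -> None:
        z = _box_to_z(box)
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = self.P @ self.H.T @ np.linalg.inv(S)
        self.x = self.x + K @ y
        self.P = (np.eye(7) - K @ self.H) @ self.P

    def set_box(self, box: BoundingBox) -> None:
        """Overwrite the positional state, keeping velocity estimates."""
        self.x[:4] = _box_to_z(box)

    @property
    def box(self) -> BoundingBox:
        return _z_to_box(self.x)


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------

@dataclass
class Track:
    """One fruit hypothesis: Kalman state plus lifecycle counters."""

    track_id: int
    kf: KalmanBoxFilter
    last_box: BoundingBox
    birth_frame: int
    birth_scale: float          # w*h at creation
    hits: int = 1               # frames with a matched detection
    frames_since_match: int = 0
    consecutive_estimates: int = 0
    counted: bool = False
    # size at the last matched frame; current estimated size is this
    # times alpha**consecutive_estimates (closed form, kept exact)
    _w_ref: float = 0.0
    _h_ref: float = 0.0

    @classmethod
    def create(cls, det: Detection, track_id: int, frame_index: int) -> "Track":
        box = det.box
        return cls(
            track_id=track_id,
            kf=KalmanBoxFilter(box),
            last_box=box,
            birth_frame=frame_index,
            birth_scale=box.w * box.h,
            _w_ref=box.w,
            _h_ref=box.h,
        )

    def predict(self) -> BoundingBox:
        return self.kf.predict()

    def update(self, det: Detection) -> None:
        self.kf.update(det.box)
        self.last_box = self.kf.box
        self.hits += 1
        self.frames_since_match = 0
        self.consecutive_estimates = 0
        self._w_ref = self.last_box.w
        self._h_ref = self.last_box.h


@dataclass(frozen=True)
class AssociationResult:
    """Partition of tracks and detections after Hungarian matching."""

    matches: list[tuple[int, int]]          # (track index, detection index)
    unmatched_tracks: list[int]
    unmatched_detections: list[int]


@dataclass(frozen=True)
class DisplacementEstimate:
    """Mean frame-to-frame displacement of the correctly tracked targets."""

    dx: float
    dy: float
    n: int

    @property
    def is_fallback(self) -> bool:
        """True when no matched track contributed (n == 0)."""
        return self.n == 0


@dataclass(frozen=True)
class TrackOutput:
    """Per-frame output record: one box with an identity."""

    frame_index: int
    track_id: int
    box: BoundingBox
    matched: bool   # True: matched detection; False: displacement/coast estimate


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def associate(
    predicted: list[BoundingBox],
    detections: list[Detection],
    iou_threshold: float,
) -> AssociationResult:
    """Hungarian minimum-cost matching under cost = 1 - IoU.

    Assignments whose IoU falls below ``iou_threshold`` are broken and
    both members reported unmatched. The three output lists partition
    the inputs.
    """
    if not predicted or not detections:
        return AssociationResult([], list(range(len(predicted))), list(range(len(detections))))
    cost = np.ones((len(predicted), len(detections)))
    for i, p in enumerate(predicted):
        for j, d in enumerate(detections):
            cost[i, j] = 1.0 - iou(p, d.box)
    rows, cols = linear_sum_assignment(cost)
    matches: list[tuple[int, int]] = []
    unmatched_t = set(range(len(predicted)))
    unmatched_d = set(range(len(detections)))
    for i, j in zip(rows, cols):
        if 1.0 - cost[i, j] >= iou_threshold:
            matches.append((int(i), int(j)))
            unmatched_t.discard(int(i))
            unmatched_d.discard(int(j))
    matches.sort(key=lambda m: m[1])
    return AssociationResult(matches, sorted(unmatched_t), sorted(unmatched_d))


def mean_displacement(pairs: list[tuple[tuple[float, float], tuple[float, float]]]) -> DisplacementEstimate:
    """Average center displacement over matched tracks.

    ``pairs`` holds (previous center, current center) per correctly
    tracked target; dx = mean(x_current - x_previous), likewise dy.
    With no pairs the estimate is flagged as a fallback.
    """
    n = len(pairs)
    if n == 0:
        return DisplacementEstimate(0.0, 0.0, 0)
    dx = sum(cur[0] - prev[0] for prev, cur in pairs) / n
    dy = sum(cur[1] - prev[1] for prev, cur in pairs) / n
    return DisplacementEstimate(dx, dy, n)


def estimate_unmatched(track: Track, disp: DisplacementEstimate, alpha: float) -> BoundingBox:
    """Propagate an unmatched track by the mean displacement with scale decay.

    The center shifts by (dx, dy); width and height decay by alpha per
    estimated frame, evaluated in closed form ``w_ref * alpha**m`` so
    that m consecutive estimates give exactly ``w0 * alpha**m``.
    Mutates the track: increments ``consecutive_estimates`` and
    ``frames_since_match`` and rewrites its box and filter state.
    """
    track.consecutive_estimates += 1
    track.frames_since_match += 1
    m = track.consecutive_estimates
    box = BoundingBox(
        track.last_box.cx + disp.dx,
        track.last_box.cy + disp.dy,
        track._w_ref * alpha**m,
        track._h_ref * alpha**m,
    )
    track.last_box = box
    track.kf.set_box(box)
    return box


def filter_region(
    detections: list[Detection],
    meta: SequenceMeta,
    region_lo: float,
    region_hi: float,
) -> list[Detection]:
    """Keep detections whose box center x lies inside the counting region.

    The interval [region_lo*W, region_hi*W] is closed on both ends;
    detection order is preserved.
    """
    lo = region_lo * meta.frame_width
    hi = region_hi * meta.frame_width
    return [d for d in detections if lo <= d.box.cx <= hi]


class Tracker:
    """Stateful frame-by-frame tracker.

    Call :meth:`step` with each frame's detections in order. Track ids
    are assigned from 1 upward and never reused.
    """

    def __init__(self, config: TrackerConfig | None = None) -> None:
        self.config = config or TrackerConfig()
        self.tracks: list[Track] = []
        self.all_tracks: list[Track] = []   # every track ever created
        self._next_id = 1
        self._last_frame = -1
        self._last_disp: DisplacementEstimate | None = None

    def _new_track(self, det: Detection, frame_index: int) -> Track:
        t = Track.create(det, self._next_id, frame_index)
        self._next_id += 1
        self.tracks.append(t)
        self.all_tracks.append(t)
        return t

    def step(self, frame_detections: list[Detection], frame_index: int) -> list[TrackOutput]:
        """Process one frame; returns the boxes and identities it holds.

        Flow: predict every live track, Hungarian-associate predictions
        with detections, then handle the three categories — matched
        (Kalman update), unmatched detections (new tracks), unmatched
        tracks (displacement estimate with scale decay, or SORT coast).
        """
        if frame_index <= self._last_frame:
            raise ValueError(
                f"frames must be processed in increasing order: got {frame_index} after {self._last_frame}"
            )
        self._last_frame = frame_index
        cfg = self.config

        predicted = [t.predict() for t in self.tracks]
        assoc = associate(predicted, frame_detections, cfg.iou_threshold)

        outputs: list[TrackOutput] = []

        # correctly matched detection boxes: displacement accumulation + update
        pairs = []
        for ti, di in assoc.matches:
            track = self.tracks[ti]
            prev_center = (track.last_box.cx, track.last_box.cy)
            det = frame_detections[di]
            track.update(det)
            pairs.append((prev_center, (det.box.cx, det.box.cy)))
            outputs.append(TrackOutput(frame_index, track.track_id, track.last_box, True))
        disp = mean_displacement(pairs)
        if not disp.is_fallback:
            self._last_disp = disp

        # unmatched detection boxes: first appearance, new tracker id
        for di in assoc.unmatched_detections:
            track = self._new_track(frame_detections[di], frame_index)
            outputs.append(TrackOutput(frame_index, track.track_id, track.last_box, True))

        # unmatched tracking boxes
        dead: list[Track] = []
        for ti in assoc.unmatched_tracks:
            track = self.tracks[ti]
            if cfg.use_displacement:
                use = disp if not disp.is_fallback else self._last_disp
                if use is not None:
                    box = estimate_unmatched(track, use, cfg.alpha)
                else:
                    # no displacement observed yet in the whole run:
                    # fall back to the track's own Kalman prediction
                    track.consecutive_estimates += 1
                    track.frames_since_match += 1
                    box = predicted[ti]
                    track.last_box = box
                    track.kf.set_box(box)
                if box.area < cfg.scale_delete_ratio * track.birth_scale:
                    dead.append(track)   # fully occluded, remove
                else:
                    outputs.append(TrackOutput(frame_index, track.track_id, box, False))
            else:
                # baseline SORT: coast on the Kalman prediction
                track.frames_since_match += 1
                track.last_box = predicted[ti]
                if track.frames_since_match > cfg.max_age:
                    dead.append(track)
                else:
                    outputs.append(TrackOutput(frame_index, track.track_id, predicted[ti], False))
        for t in dead:
            self.tracks.remove(t)

        for t in self.tracks:
            if not t.counted and t.hits >= cfg.min_hits:
                t.counted = True
        outputs.sort(key=lambda o: o.track_id)
        ids = [o.track_id for o in outputs]
        assert len(ids) == len(set(ids)), "duplicate id in per-frame output"
        return outputs

    @property
    def fruit_count(self) -> int:
        """Number of track identities with hits >= min_hits."""
        return sum(1 for t in self.all_tracks if t.hits >= self.config.min_hits)


def outputs_to_track_boxes(
    outputs: list[TrackOutput],
    include_ids: set[int] | None = None,
) -> dict[int, dict[int, BoundingBox]]:
    """Group per-frame outputs as {track id: {frame index: box}}.

    ``include_ids`` restricts the result (e.g. to counted tracks).
    """
    tracks: dict[int, dict[int, BoundingBox]] = {}
    for o in outputs:
        if include_ids is None or o.track_id in include_ids:
            tracks.setdefault(o.track_id, {})[o.frame_index] = o.box
    return tracks


def run_sequence(
    frames: list[list[Detection]],
    meta: SequenceMeta,
    config: TrackerConfig | None = None,
) -> tuple[list[Track], list[TrackOutput], int]:
    """Track a whole sequence and count fruits.

    Applies the counting-region pre-filter when ``config.use_region``,
    then steps the tracker through every frame. Returns (all tracks
    ever created, per-frame outputs, fruit count). Deterministic given
    inputs and config; an empty sequence yields count 0.
    """
    config = config or TrackerConfig()
    tracker = Tracker(config)
    outputs: list[TrackOutput] = []
    for frame_index, dets in enumerate(frames):
        if config.use_region:
            dets = filter_region(dets, meta, config.region_lo, config.region_hi)
        outputs.extend(tracker.step(dets, frame_index))
    return tracker.all_tracks, outputs, tracker.fruit_count
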