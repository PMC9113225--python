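"""Synthetic orchard video-sequence generator.

Emulates the geometry of tracking-by-detection fruit counting: fruits
are stationary in the world while the camera translates horizontally at
uniform speed, so every fruit crosses the image at exactly
``camera_speed`` pixels per frame. Occlusion follows a seven-condition
taxonomy (A-G) over the three stages of a fruit's transit — initial,
intermediate and leaving thirds — where a condition marks each stage as
occluded or clear (A = never occluded; E = occluded only mid-transit;
etc.). An occluded stage suppresses the fruit's detection for a
sub-span placed centrally inside that stage. Detector imperfection is
modelled separately: independent misses, Poisson false positives and
Gaussian box jitter.

Everything is deterministic given the scene seed, which makes the
generator the fixture source for tracker and counting tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import BoundingBox, Detection, SequenceMeta

__all__ = [
    "OCCLUSION_CONDITIONS",
    "DEFAULT_OCCLUSION_MIX",
    "SceneConfig",
    "Fruit",
    "Scene",
    "GroundTruthTrack",
    "sample_scene",
    "render_ground_truth",
    "apply_detector_noise",
    "expected_region_count",
]

# condition -> (initial occluded, intermediate occluded, leaving occluded)
OCCLUSION_CONDITIONS: dict[str, tuple[bool, bool, bool]] = {
    "A": (False, False, False),
    "B": (True, False, False),
    "C": (True, False, True),
    "D": (False, False, True),
    "E": (False, True, False),
    "F": (False, True, True),
    "G": (True, True, False),
}

# entry-edge conditions dominate in real orchard sequences
DEFAULT_OCCLUSION_MIX: dict[str, float] = {
    "A": 0.40, "B": 0.15, "C": 0.10, "D": 0.15, "E": 0.10, "F": 0.05, "G": 0.05,
}


@dataclass(frozen=True)
class SceneConfig:
    """Parameters of a synthetic orchard scene.

    Fruits enter at the right frame edge and exit left (camera moving
    right). ``fruit_w_mean/sd`` follow the 11-50 px width range of
    labelled orchard fruit; ``occl_span`` is the fraction of an
    occluded transit stage during which the detection is suppressed.
    """

    n_fruits: int = 30
    frame_width: int = 1920
    frame_height: int = 1080
    camera_speed: float = 4.0           # pixels/frame, horizontal
    fruit_w_mean: float = 28.0
    fruit_w_sd: float = 8.0
    fruit_w_min: float = 12.0
    fruit_w_max: float = 55.0
    occlusion_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_OCCLUSION_MIX))
    occl_span: float = 0.6
    miss_rate: float = 0.0
    fp_rate: float = 0.0
    jitter_sd: float = 0.0
    gradual_shrink: bool = False        # shrink the box over 3 frames into an occlusion
    entry_spread: float = 400.0         # pixels over which fruit entries are staggered
    seed: int = 0

    def __post_init__(self) -> None:
        if self.camera_speed == 0:
            raise ValueError("camera_speed must be nonzero")
        if not (0.0 <= self.miss_rate <= 1.0):
            raise ValueError("miss_rate must be in [0, 1]")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be non-negative")
        unknown = set(self.occlusion_mix) - set(OCCLUSION_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown occlusion conditions {sorted(unknown)}")
        total = sum(self.occlusion_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"occlusion_mix proportions must sum to 1, got {total}")

    @property
    def meta(self) -> SequenceMeta:
        return SequenceMeta(self.frame_width, self.frame_height, self.n_frames)

    @property
    def n_frames(self) -> int:
        # enough frames for the last-entering fruit to fully cross
        span = self.entry_spread + self.frame_width + self.fruit_w_max
        return int(math.ceil(span / abs(self.camera_speed))) + 1


@dataclass(frozen=True)
class Fruit:
    """One stationary fruit: entry position, vertical placement, size."""

    fruit_id: int
    x0: float           # image center x at frame 0 (>= frame width: not yet entered)
    cy: float
    w: float
    h: float
    condition: str


@dataclass(frozen=True)
class Scene:
    fruits: tuple[Fruit, ...]
    config: SceneConfig


@dataclass(frozen=True)
class GroundTruthTrack:
    """Per-frame boxes of one fruit while on screen and unoccluded."""

    fruit_id: int
    condition: str
    boxes: dict[int, BoundingBox]       # frame index -> box (visible frames only)
    occluded_frames: frozenset[int]     # on-screen frames suppressed by occlusion


def sample_scene(config: SceneConfig) -> Scene:
    """Draw fruit positions, sizes and occlusion conditions. Seed-deterministic."""
    rng = np.random.default_rng(config.seed)
    conditions = sorted(config.occlusion_mix)
    probs = np.array([config.occlusion_mix[c] for c in conditions])
    fruits = []
    for i in range(config.n_fruits):
        w = float(np.clip(rng.normal(config.fruit_w_mean, config.fruit_w_sd),
                          config.fruit_w_min, config.fruit_w_max))
        h = float(np.clip(w * rng.normal(1.0, 0.12), config.fruit_w_min, config.fruit_w_max))
        cy = float(rng.uniform(0.12 * config.frame_height, 0.88 * config.frame_height))
        x0 = float(config.frame_width + w / 2 + rng.uniform(0.0, config.entry_spread))
        cond = str(rng.choice(conditions, p=probs))
        fruits.append(Fruit(i + 1, x0, cy, w, h, cond))
    return Scene(tuple(fruits), config)


def _occluded_x_bands(fruit: Fruit, config: SceneConfig) -> list[tuple[float, float]]:
    """Image-x intervals (by box center) where the fruit's detection is suppressed.

    The transit (center x from W down to 0) is split into initial,
    intermediate and leaving thirds; a stage marked occluded by the
    fruit's condition hides the fruit over the central ``occl_span``
    fraction of that stage.
    """
    W = config.frame_width
    flags = OCCLUSION_CONDITIONS[fruit.condition]
    # stage order along decreasing x: initial (2W/3..W), intermediate, leaving
    stages = [(2 * W / 3, W), (W / 3, 2 * W / 3), (0.0, W / 3)]
    bands = []
    for (lo, hi), occluded in zip(stages, (flags[0], flags[1], flags[2])):
        if occluded:
            margin = (1.0 - config.occl_span) / 2 * (hi - lo)
            bands.append((lo + margin, hi - margin))
    return bands


def render_ground_truth(scene: Scene) -> list[GroundTruthTrack]:
    """Project every fruit into image coordinates frame by frame.

    Consecutive visible boxes of a fruit differ by exactly
    (-camera_speed, 0); boxes are omitted while the fruit is off screen
    or inside an occluded band (optionally shrinking over the 3 frames
    entering an occlusion when ``gradual_shrink`` is set).
    """
    config = scene.config
    tracks = []
    for fruit in scene.fruits:
        bands = _occluded_x_bands(fruit, config)
        boxes: dict[int, BoundingBox] = {}
        occluded: set[int] = set()
        for t in range(config.n_frames):
            cx = fruit.x0 - config.camera_speed * t
            if not (0.0 <= cx <= config.frame_width):
                continue
            in_band = any(lo <= cx <= hi for lo, hi in bands)
            if in_band:
                occluded.add(t)
                continue
            w, h = fruit.w, fruit.h
            if config.gradual_shrink:
                # approaching an occluded band: pixel area gradually decreases
                for lo, hi in bands:
                    dist = min(abs(cx - lo), abs(cx - hi))
                    steps = dist / config.camera_speed
                    if steps < 3:
                        factor = (math.floor(steps) + 1) / 4
                        w, h = fruit.w * factor, fruit.h * factor
            boxes[t] = BoundingBox(cx, fruit.cy, w, h)
        tracks.append(GroundTruthTrack(fruit.fruit_id, fruit.condition, boxes, frozenset(occluded)))
    return tracks


def apply_detector_noise(
    gt_tracks: list[GroundTruthTrack],
    config: SceneConfig,
) -> list[list[Detection]]:
    """Corrupt ground truth into per-frame detection lists.

    Each visible box is dropped with probability ``miss_rate``; centers
    and sizes are perturbed with Gaussian noise of ``jitter_sd`` pixels;
    Poisson(``fp_rate``) spurious uniformly placed boxes are added per
    frame. Deterministic given the scene seed.
    """
    rng = np.random.default_rng([config.seed, 1])
    frames: list[list[Detection]] = [[] for _ in range(config.n_frames)]
    for track in gt_tracks:
        for t in sorted(track.boxes):
            if rng.uniform() < config.miss_rate:
                continue
            box = track.boxes[t]
            if config.jitter_sd > 0:
                cx = box.cx + rng.normal(0, config.jitter_sd)
                cy = box.cy + rng.normal(0, config.jitter_sd)
                w = max(2.0, box.w + rng.normal(0, config.jitter_sd))
                h = max(2.0, box.h + rng.normal(0, config.jitter_sd))
                box = BoundingBox(cx, cy, w, h)
            frames[t].append(Detection(t, box, 1.0))
    for t in range(config.n_frames):
        for _ in range(rng.poisson(config.fp_rate)):
            w = float(rng.uniform(config.fruit_w_min, config.fruit_w_max))
            h = float(rng.uniform(config.fruit_w_min, config.fruit_w_max))
            cx = float(rng.uniform(0, config.frame_width))
            cy = float(rng.uniform(0, config.frame_height))
            frames[t].append(Detection(t, BoundingBox(cx, cy, w, h), float(rng.uniform(0.3, 1.0))))
    return frames


def expected_region_count(
    gt_tracks: list[GroundTruthTrack],
    config: SceneConfig,
    region_lo: float = 0.2,
    region_hi: float = 0.8,
    min_visible_frames: int = 1,
) -> int:
    """Fruits countable under the region strategy.

    A fruit counts when it is visible (on screen, unoccluded) for at
    least ``min_visible_frames`` frames while its center lies inside
    [region_lo*W, region_hi*W]. Serves as the counting oracle.
    """
    lo = region_lo * config.frame_width
    hi = region_hi * config.frame_width
    n = 0
    for track in gt_tracks:
        visible = sum(1 for box in track.boxes.values() if lo <= box.cx <= hi)
        if visible >= min_visible_frames:
            n += 1
    return n
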