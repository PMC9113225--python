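"""Geometry primitives and the shared data model.

Coordinate convention: image origin at the top-left corner, x increases
rightward, y increases downward, continuous (real-valued) pixel
coordinates. The canonical box representation is center-size ``(cx, cy,
w, h)`` because the tracker's displacement and scale-decay arithmetic is
stated on box centers and widths/heights.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel frame coordinates, center-size form.

    Attributes
    ----------
    cx, cy : float
        Box center (pixels); x rightward, y downward.
    w, h : float
        Width and height (pixels), strictly positive.
    """

    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if not (self.w > 0 and self.h > 0):
            raise ValueError(f"box dimensions must be positive, got w={self.w}, h={self.h}")

    @property
    def left(self) -> float:
        return self.cx - self.w / 2

    @property
    def top(self) -> float:
        return self.cy - self.h / 2

    @property
    def right(self) -> float:
        return self.cx + self.w / 2

    @property
    def bottom(self) -> float:
        return self.cy + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h

    @classmethod
    def from_corner(cls, left: float, top: float, w: float, h: float) -> "BoundingBox":
        return cls(left + w / 2, top + h / 2, w, h)

    @classmethod
    def from_corners(cls, x1: float, y1: float, x2: float, y2: float) -> "BoundingBox":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1)


@dataclass(frozen=True)
class Detection:
    """One detector output on one frame."""

    frame_index: int
    box: BoundingBox
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError(f"frame_index must be >= 0, got {self.frame_index}")
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be in [0,1], got {self.confidence}")


@dataclass(frozen=True)
class SequenceMeta:
    """Frame geometry and timing of a video sequence.

    Defaults follow a 1920x1080 orchard video at 30 fps.
    """

    frame_width: int = 1920
    frame_height: int = 1080
    n_frames: int = 1
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.frame_width <= 0 or self.frame_height <= 0 or self.n_frames <= 0:
            raise ValueError("frame_width, frame_height and n_frames must be positive")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two boxes; 0 when disjoint, 1 when identical."""
    ix = min(a.right, b.right) - max(a.left, b.left)
    iy = min(a.bottom, b.bottom) - max(a.top, b.top)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


_REPRESENTATIONS = ("center-size", "corner-size", "corner-corner")


def convert_box(box: tuple[float, float, float, float], src: str, dst: str) -> tuple[float, float, float, float]:
    """Convert a 4-tuple box between representations.

    Representations: ``center-size`` (cx, cy, w, h), ``corner-size``
    (left, top, w, h), ``corner-corner`` (x1, y1, x2, y2). The
    conversion is lossless: round-tripping returns the original tuple.
    """
    for name in (src, dst):
        if name not in _REPRESENTATIONS:
            raise ValueError(f"unknown box representation {name!r}; expected one of {_REPRESENTATIONS}")
    a, b, c, d = box
    if src == "center-size":
        cx, cy, w, h = a, b, c, d
    elif src == "corner-size":
        cx, cy, w, h = a + c / 2, b + d / 2, c, d
    else:
        cx, cy, w, h = (a + c) / 2, (b + d) / 2, c - a, d - b
    if dst == "center-size":
        return (cx, cy, w, h)
    if dst == "corner-size":
        return (cx - w / 2, cy - h / 2, w, h)
    return (cx - w / 2, cy - h / 2, cx + w / 2, cy + h / 2)
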