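"""File formats: MOT-challenge CSV, YOLO label files, YAML run config.

Detections and tracks are interchanged in the 10-column MOT-challenge
CSV dialect ``frame,id,bb_left,bb_top,bb_width,bb_height,conf,x,y,z``
with 1-based frame numbers on disk (0-based in memory) and ``-1`` in
unused columns. Anchor-clustering input uses the YOLO label dialect:
one text file per image, lines ``class cx cy w h`` normalized to [0,1].
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BoundingBox, Detection, SequenceMeta
from .tracking import TrackerConfig, TrackOutput

__all__ = [
    "read_detections",
    "write_detections",
    "read_tracks",
    "write_tracks",
    "read_yolo_labels",
    "load_config",
]

_MOT_COLUMNS = ["frame", "id", "bb_left", "bb_top", "bb_width", "bb_height", "conf", "x", "y", "z"]


def _read_mot(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.stat().st_size == 0:
        return pd.DataFrame(columns=_MOT_COLUMNS)
    try:
        df = pd.read_csv(path, header=None, names=_MOT_COLUMNS)
    except Exception as exc:  # noqa: BLE001 - report file-level parse failures uniformly
        raise ValueError(f"{path}: not a parseable MOT CSV file ({exc})") from exc
    bad = df[_MOT_COLUMNS[:7]].isna().any(axis=1)
    if bad.any():
        raise ValueError(f"{path}: malformed line {int(bad.idxmax()) + 1} (expected 10 numeric fields)")
    if (df["frame"] < 1).any():
        raise ValueError(f"{path}: frame numbers must be >= 1")
    if (df["bb_width"] <= 0).any() or (df["bb_height"] <= 0).any():
        line = int((df["bb_width"] <= 0).idxmax() if (df["bb_width"] <= 0).any()
                   else (df["bb_height"] <= 0).idxmax()) + 1
        raise ValueError(f"{path}: nonpositive box dimensions at line {line}")
    return df


def read_detections(
    path: str | Path,
    n_frames: int | None = None,
    frame_width: int | None = None,
    frame_height: int | None = None,
) -> tuple[list[list[Detection]], SequenceMeta]:
    """Read a MOT detection file into per-frame lists plus inferred meta.

    Frames absent from the file yield empty lists; the 1-based frame
    numbers on disk become 0-based indices. Frame geometry not supplied
    is inferred from the maximal box extents.
    """
    df = _read_mot(path)
    n = n_frames if n_frames is not None else (int(df["frame"].max()) if len(df) else 0)
    frames: list[list[Detection]] = [[] for _ in range(n)]
    for row in df.itertuples(index=False):
        box = BoundingBox.from_corner(row.bb_left, row.bb_top, row.bb_width, row.bb_height)
        conf = min(max(float(row.conf), 0.0), 1.0) if row.conf >= 0 else 1.0
        frames[int(row.frame) - 1].append(Detection(int(row.frame) - 1, box, conf))
    if len(df):
        width = frame_width or int(np.ceil((df["bb_left"] + df["bb_width"]).max()))
        height = frame_height or int(np.ceil((df["bb_top"] + df["bb_height"]).max()))
        meta = SequenceMeta(max(width, 1), max(height, 1), max(n, 1))
    else:
        meta = SequenceMeta(frame_width or 1, frame_height or 1, max(n, 1))
    return frames, meta


def write_detections(path: str | Path, frames: list[list[Detection]]) -> None:
    """Write per-frame detections as MOT CSV (id column = -1)."""
    rows = []
    for t, dets in enumerate(frames):
        for d in dets:
            b = d.box
            rows.append((t + 1, -1, b.left, b.top, b.w, b.h, d.confidence, -1, -1, -1))
    pd.DataFrame(rows, columns=_MOT_COLUMNS).to_csv(path, header=False, index=False)


def write_tracks(path: str | Path, outputs: list[TrackOutput]) -> None:
    """Write tracker outputs as MOT CSV, sorted by (frame, id)."""
    rows = []
    for o in sorted(outputs, key=lambda o: (o.frame_index, o.track_id)):
        b = o.box
        rows.append((o.frame_index + 1, o.track_id, b.left, b.top, b.w, b.h,
                     1.0 if o.matched else 0.0, -1, -1, -1))
    pd.DataFrame(rows, columns=_MOT_COLUMNS).to_csv(path, header=False, index=False)


def read_tracks(path: str | Path) -> dict[int, dict[int, BoundingBox]]:
    """Read a MOT track (or gt) file as {track id: {frame index: box}}."""
    df = _read_mot(path)
    tracks: dict[int, dict[int, BoundingBox]] = {}
    for row in df.itertuples(index=False):
        box = BoundingBox.from_corner(row.bb_left, row.bb_top, row.bb_width, row.bb_height)
        tracks.setdefault(int(row.id), {})[int(row.frame) - 1] = box
    return tracks


def read_yolo_labels(directory: str | Path) -> np.ndarray:
    """Collect (width, height) pixel-free normalized dims from YOLO label files.

    Reads every ``*.txt`` file under ``directory`` (lines: ``class cx
    cy w h``, normalized); returns an (n, 2) array of (w, h).
    """
    dims = []
    for path in sorted(Path(directory).glob("*.txt")):
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            w, h = float(parts[3]), float(parts[4])
            if w <= 0 or h <= 0:
                raise ValueError(f"{path}:{lineno}: nonpositive box dimensions")
            dims.append((w, h))
    return np.array(dims, dtype=float).reshape(-1, 2)


_CONFIG_KEYS = {
    "iou_threshold", "alpha", "scale_delete_ratio", "min_hits",
    "region_lo", "region_hi", "use_region", "use_displacement", "max_age",
}


def load_config(path: str | Path) -> TrackerConfig:
    """Load a tracker config from YAML; unknown keys are rejected."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a YAML mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    return TrackerConfig(**data)
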