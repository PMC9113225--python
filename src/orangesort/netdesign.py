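"""Network-design analytics: receptive fields, anchor clustering, mosaic.

The theoretical receptive field of the k-th convolutional layer is

    R_k = 1 + sum_{j=1..k} (F_j - 1) * prod_{i=0..j-1} S_i,   S_0 = 1,

with kernel size F_j and stride S_j per layer. Detection branches are
placed where the receptive field first covers the target scale; anchor
shapes come from k-means clustering of labelled box dimensions; mosaic
augmentation composites four labelled images into one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "ConvLayerSpec",
    "NetworkSpec",
    "AnchorSet",
    "receptive_field",
    "darknet53_spec",
    "branch_for_target",
    "kmeans_anchors",
    "mosaic",
]


@dataclass(frozen=True)
class ConvLayerSpec:
    """One convolutional layer: square kernel size and stride."""

    kernel: int
    stride: int

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be positive integers")


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered conv-layer list, 1-indexed in all layer arithmetic.

    Residual shortcut additions do not appear: elementwise adds leave
    the receptive field unchanged, so only convolutions are counted.
    """

    layers: tuple[ConvLayerSpec, ...]

    def __post_init__(self) -> None:
        if len(self.layers) == 0:
            raise ValueError("network spec must contain at least one layer")

    def __len__(self) -> int:
        return len(self.layers)


@dataclass(frozen=True)
class AnchorSet:
    """k anchor (width, height) pairs sorted by area."""

    anchors: tuple[tuple[float, float], ...]


def receptive_field(spec: NetworkSpec, k: int) -> int:
    """Receptive field size R_k of the k-th convolutional layer (1-based)."""
    if not (1 <= k <= len(spec)):
        raise ValueError(f"layer index {k} out of range 1..{len(spec)}")
    r = 1
    jump = 1  # product of strides of layers 0..j-1 (S_0 = 1)
    for layer in spec.layers[:k]:
        r += (layer.kernel - 1) * jump
        jump *= layer.stride
    return r


def darknet53_spec() -> NetworkSpec:
    """The standard DarkNet53 backbone as a 52-conv-layer spec.

    Stem 3x3/1, then five downsampling 3x3/2 convolutions, each
    followed by 1, 2, 8, 8 and 4 residual blocks of [1x1/1, 3x3/1].
    """
    layers: list[ConvLayerSpec] = [ConvLayerSpec(3, 1)]
    for n_blocks in (1, 2, 8, 8, 4):
        layers.append(ConvLayerSpec(3, 2))
        for _ in range(n_blocks):
            layers.append(ConvLayerSpec(1, 1))
            layers.append(ConvLayerSpec(3, 1))
    return NetworkSpec(tuple(layers))


def branch_for_target(spec: NetworkSpec, target_max_dim: float) -> tuple[int, bool]:
    """Smallest layer index whose receptive field covers the target.

    Returns ``(k, covered)`` where k is the first layer with
    R_k >= target_max_dim. When even the final layer's receptive field
    is smaller than the target, the final index is returned with
    ``covered=False``.
    """
    if target_max_dim <= 0:
        raise ValueError("target dimension must be positive")
    for k in range(1, len(spec) + 1):
        if receptive_field(spec, k) >= target_max_dim:
            return k, True
    return len(spec), False


def kmeans_anchors(
    dims: np.ndarray,
    k: int,
    seed: int = 0,
    metric: str = "euclidean",
) -> AnchorSet:
    """Cluster labelled box (width, height) pairs into k anchor shapes.

    ``metric='euclidean'`` runs standard k-means (k-means++ init, fixed
    seed); ``metric='iou'`` runs Lloyd iterations under the 1 - IoU
    distance common in anchor estimation, where IoU is evaluated on
    boxes sharing a corner. Centroids are returned sorted by area.
    """
    dims = np.asarray(dims, dtype=float)
    if dims.ndim != 2 or dims.shape[1] != 2:
        raise ValueError("dims must be an (n, 2) array of (width, height)")
    if np.any(dims <= 0):
        raise ValueError("box dimensions must be positive")
    if len(dims) < k:
        raise ValueError(f"need at least k={k} boxes, got {len(dims)}")
    if metric == "euclidean":
        km = KMeans(n_clusters=k, init="k-means++", n_init=10, random_state=seed)
        km.fit(dims)
        centers = km.cluster_centers_
    elif metric == "iou":
        centers = _kmeans_iou(dims, k, seed)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    order = np.argsort(centers[:, 0] * centers[:, 1])
    return AnchorSet(tuple((float(w), float(h)) for w, h in centers[order]))


def _pairwise_iou_wh(dims: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """IoU of (w,h) boxes anchored at a common corner, (n, k)."""
    iw = np.minimum(dims[:, None, 0], centers[None, :, 0])
    ih = np.minimum(dims[:, None, 1], centers[None, :, 1])
    inter = iw * ih
    union = dims[:, 0:1] * dims[:, 1:2] + (centers[:, 0] * centers[:, 1])[None, :] - inter
    return inter / union


def _kmeans_iou(dims: np.ndarray, k: int, seed: int, max_iter: int = 300) -> np.ndarray:
    rng = np.random.default_rng(seed)
    centers = dims[rng.choice(len(dims), size=k, replace=False)].copy()
    labels = np.zeros(len(dims), dtype=int)
    for _ in range(max_iter):
        new_labels = np.argmax(_pairwise_iou_wh(dims, centers), axis=1)
        if np.array_equal(new_labels, labels) and _ > 0:
            break
        labels = new_labels
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = dims[mask].mean(axis=0)
    return centers


def _resize_nearest(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    h, w = img.shape[:2]
    rows = np.minimum((np.arange(out_h) * h / out_h).astype(int), h - 1)
    cols = np.minimum((np.arange(out_w) * w / out_w).astype(int), w - 1)
    return img[rows][:, cols]


def mosaic(
    images: list[np.ndarray],
    boxes: list[np.ndarray],
    output_size: int,
    seed: int = 0,
    center_jitter: float = 0.25,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float, float, float]]]:
    """Composite four labelled images into one 2x2 mosaic.

    The collage center is jittered uniformly within the central band of
    the canvas; each image is resized (nearest neighbour) into its
    quadrant and its corner-corner boxes ``(x1, y1, x2, y2)`` mapped by
    the same affine, clipped to the canvas, dropping boxes left empty.

    Returns (canvas, remapped boxes, per-quadrant affines as
    (scale_x, scale_y, offset_x, offset_y)).
    """
    if len(images) != 4 or len(boxes) != 4:
        raise ValueError("mosaic requires exactly 4 images with their box arrays")
    S = output_size
    rng = np.random.default_rng(seed)
    lo, hi = center_jitter * S, (1 - center_jitter) * S
    cx = int(rng.uniform(lo, hi))
    cy = int(rng.uniform(lo, hi))
    canvas = np.zeros((S, S) + images[0].shape[2:], dtype=images[0].dtype)
    quads = [(0, 0, cx, cy), (cx, 0, S, cy), (0, cy, cx, S), (cx, cy, S, S)]
    out_boxes: list[np.ndarray] = []
    affines: list[tuple[float, float, float, float]] = []
    for img, bxs, (x0, y0, x1, y1) in zip(images, boxes, quads):
        qh, qw = y1 - y0, x1 - x0
        canvas[y0:y1, x0:x1] = _resize_nearest(img, qh, qw)
        sx, sy = qw / img.shape[1], qh / img.shape[0]
        affines.append((sx, sy, float(x0), float(y0)))
        if len(bxs) == 0:
            continue
        b = np.asarray(bxs, dtype=float).copy()
        b[:, [0, 2]] = b[:, [0, 2]] * sx + x0
        b[:, [1, 3]] = b[:, [1, 3]] * sy + y0
        b[:, [0, 2]] = np.clip(b[:, [0, 2]], 0, S)
        b[:, [1, 3]] = np.clip(b[:, [1, 3]], 0, S)
        keep = (b[:, 2] > b[:, 0]) & (b[:, 3] > b[:, 1])
        out_boxes.append(b[keep])
    remapped = np.concatenate(out_boxes, axis=0) if out_boxes else np.zeros((0, 4))
    return canvas, remapped, affines
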