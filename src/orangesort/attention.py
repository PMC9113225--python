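"""Reference numeric implementation of a dual-attention fusion block.

Plain-array (H, W, C) math for a channel + spatial attention multiscale
fusion module, for verifying the published equations — no training, no
autograd. Channel attention is squeeze-and-excitation style: global
average pooling z_c, bottleneck S = sigmoid(W2 · relu(W1 · z)), per-
channel rescale y_c = s_c * x_c. Spatial attention stacks the channel-
wise mean and max maps, convolves them with a 7x7 kernel (zero "same"
padding), and multiplies the sigmoid weight map onto the feature.
Fusion: nearest-neighbour 2x upsampling of the deep feature, channel
attention on each input independently, channel concatenation, spatial
attention on the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate2d

__all__ = [
    "ChannelAttentionParams",
    "SpatialAttentionParams",
    "global_pool",
    "channel_weights",
    "channel_scale",
    "spatial_attention",
    "upsample2x",
    "dual_attention_fuse",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ChannelAttentionParams:
    """Bottleneck weights of the channel-attention branch.

    W1: (c/r, c) reduction, W2: (c, c/r) expansion; r is the reduction
    ratio (default 16, the squeeze-excitation convention).
    """

    W1: np.ndarray
    W2: np.ndarray

    def __post_init__(self) -> None:
        if self.W1.ndim != 2 or self.W2.ndim != 2 or self.W1.shape[0] != self.W2.shape[1] \
                or self.W1.shape[1] != self.W2.shape[0]:
            raise ValueError("W1 (c/r, c) and W2 (c, c/r) shapes are inconsistent")

    @classmethod
    def zeros(cls, channels: int, r: int = 16) -> "ChannelAttentionParams":
        hidden = max(1, channels // r)
        return cls(np.zeros((hidden, channels)), np.zeros((channels, hidden)))

    @classmethod
    def random(cls, channels: int, r: int = 16, seed: int = 0) -> "ChannelAttentionParams":
        rng = np.random.default_rng(seed)
        hidden = max(1, channels // r)
        return cls(rng.normal(scale=0.1, size=(hidden, channels)),
                   rng.normal(scale=0.1, size=(channels, hidden)))


@dataclass(frozen=True)
class SpatialAttentionParams:
    """7x7x2 convolution kernel of the spatial-attention branch."""

    kernel: np.ndarray  # (7, 7, 2)

    def __post_init__(self) -> None:
        if self.kernel.shape != (7, 7, 2):
            raise ValueError(f"kernel must be (7, 7, 2), got {self.kernel.shape}")

    @classmethod
    def zeros(cls) -> "SpatialAttentionParams":
        return cls(np.zeros((7, 7, 2)))

    @classmethod
    def random(cls, seed: int = 0) -> "SpatialAttentionParams":
        return cls(np.random.default_rng(seed).normal(scale=0.1, size=(7, 7, 2)))


def global_pool(X: np.ndarray) -> np.ndarray:
    """Squeeze: z_c = mean over H x W of channel c. (H, W, C) -> (C,)."""
    if X.ndim != 3:
        raise ValueError("feature map must be (H, W, C)")
    return X.mean(axis=(0, 1))


def channel_weights(z: np.ndarray, params: ChannelAttentionParams) -> np.ndarray:
    """Excite: s = sigmoid(W2 · relu(W1 · z)), entries strictly in (0, 1)."""
    if z.shape[0] != params.W1.shape[1]:
        raise ValueError(f"channel count {z.shape[0]} does not match W1 {params.W1.shape}")
    return _sigmoid(params.W2 @ np.maximum(params.W1 @ z, 0.0))


def channel_scale(X: np.ndarray, s: np.ndarray) -> np.ndarray:
    """Rescale each channel: y_c = s_c * x_c."""
    if X.shape[2] != s.shape[0]:
        raise ValueError("weight vector length must equal channel count")
    return X * s[None, None, :]


def spatial_attention(Y: np.ndarray, params: SpatialAttentionParams) -> np.ndarray:
    """Spatial reweighting of a feature map.

    Channel-wise mean and max maps are stacked into a 2-channel map,
    convolved with the 7x7 kernel under zero "same" padding, passed
    through a sigmoid, and broadcast-multiplied onto Y.
    """
    pooled = np.stack([Y.mean(axis=2), Y.max(axis=2)], axis=2)
    response = sum(
        correlate2d(pooled[:, :, c], params.kernel[:, :, c], mode="same", boundary="fill")
        for c in range(2)
    )
    return Y * _sigmoid(response)[:, :, None]


def upsample2x(X: np.ndarray) -> np.ndarray:
    """Nearest-neighbour 2x spatial upsampling of (H, W, C)."""
    return np.repeat(np.repeat(X, 2, axis=0), 2, axis=1)


def dual_attention_fuse(
    X1: np.ndarray,
    X2: np.ndarray,
    ca1: ChannelAttentionParams,
    ca2: ChannelAttentionParams,
    sa: SpatialAttentionParams,
) -> np.ndarray:
    """Fuse a shallow (H, W, c1) and a deep (H/2, W/2, c2) feature map.

    Output is (H, W, c1 + c2). The two channel-attention branches use
    independent parameter sets.
    """
    if X2.shape[0] * 2 != X1.shape[0] or X2.shape[1] * 2 != X1.shape[1]:
        raise ValueError(
            f"deep feature spatial dims {X2.shape[:2]} must be half of shallow {X1.shape[:2]}"
        )
    X2u = upsample2x(X2)
    Y1 = channel_scale(X1, channel_weights(global_pool(X1), ca1))
    Y2 = channel_scale(X2u, channel_weights(global_pool(X2u), ca2))
    Y = np.concatenate([Y1, Y2], axis=2)
    return spatial_attention(Y, sa)
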