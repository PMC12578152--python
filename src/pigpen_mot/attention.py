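"""Forward pass of the Convolutional Block Attention Module (CBAM) in NumPy.

CBAM refines a feature map in two sequential gating stages: channel
attention (CAM) squeezes the spatial grid with average and max pooling,
pushes both pooled vectors through a shared two-layer MLP (reduction ratio
r, ReLU between layers) and sigmoids their sum into a per-channel gate;
spatial attention (SAM) stacks the channel-wise mean and max maps into a
2-channel image, convolves with a 7x7 kernel (zero padding 3, stride 1) and
sigmoids into an HxW gate.  Weights here are supplied, never trained: this
is pure array math for inspecting and testing the mechanism outside any
deep-learning framework.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import convolve2d

__all__ = [
    "CbamWeights",
    "random_cbam_weights",
    "save_cbam_weights",
    "load_cbam_weights",
    "channel_attention",
    "spatial_attention",
    "cbam_forward",
]

_SPATIAL_KERNEL_SIZE = 7


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CbamWeights:
    """CBAM parameters: shared channel MLP + 7x7 spatial convolution.

    mlp_hidden has shape (C/r, C), mlp_out (C, C/r); the same MLP serves the
    average- and max-pooled branches.  spatial_kernel has shape (7, 7, 2),
    the trailing axis indexing the [mean; max] channel-pooling stack.
    """

    mlp_hidden: np.ndarray
    mlp_out: np.ndarray
    reduction_ratio: int
    spatial_kernel: np.ndarray
    spatial_bias: float = 0.0

    def __post_init__(self) -> None:
        hid, c = self.mlp_hidden.shape
        c2, hid2 = self.mlp_out.shape
        if c != c2 or hid != hid2:
            raise ValueError(
                f"MLP shapes inconsistent: hidden {self.mlp_hidden.shape}, out {self.mlp_out.shape}"
            )
        if self.reduction_ratio < 1 or c % self.reduction_ratio != 0:
            raise ValueError(f"channels {c} must be divisible by reduction ratio {self.reduction_ratio}")
        if hid != c // self.reduction_ratio:
            raise ValueError(f"hidden width {hid} != C/r = {c // self.reduction_ratio}")
        k = self.spatial_kernel.shape
        if k != (_SPATIAL_KERNEL_SIZE, _SPATIAL_KERNEL_SIZE, 2):
            raise ValueError(f"spatial kernel must be 7x7x2, got {k}")

    @property
    def channels(self) -> int:
        return self.mlp_hidden.shape[1]


def random_cbam_weights(channels: int, reduction_ratio: int = 2, seed: int = 0, std: float = 0.1) -> CbamWeights:
    """Seeded Gaussian weights for tests and demonstrations."""
    rng = np.random.default_rng(seed)
    hid = channels // reduction_ratio
    if hid < 1:
        raise ValueError("reduction ratio too large for channel count")
    return CbamWeights(
        mlp_hidden=rng.normal(0.0, std, (hid, channels)),
        mlp_out=rng.normal(0.0, std, (channels, hid)),
        reduction_ratio=reduction_ratio,
        spatial_kernel=rng.normal(0.0, std, (_SPATIAL_KERNEL_SIZE, _SPATIAL_KERNEL_SIZE, 2)),
        spatial_bias=float(rng.normal(0.0, std)),
    )


def save_cbam_weights(path: str | Path, w: CbamWeights) -> None:
    """Serialize weights as a flat named-array archive (NPZ layout)."""
    np.savez(
        path,
        mlp_hidden=w.mlp_hidden,
        mlp_out=w.mlp_out,
        reduction_ratio=np.array(w.reduction_ratio),
        spatial_kernel=w.spatial_kernel,
        spatial_bias=np.array(w.spatial_bias),
    )


def load_cbam_weights(path: str | Path) -> CbamWeights:
    with np.load(path) as z:
        return CbamWeights(
            mlp_hidden=z["mlp_hidden"],
            mlp_out=z["mlp_out"],
            reduction_ratio=int(z["reduction_ratio"]),
            spatial_kernel=z["spatial_kernel"],
            spatial_bias=float(z["spatial_bias"]),
        )


def _validate_feature(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError(f"feature map must be C x H x W, got shape {f.shape}")
    if not np.all(np.isfinite(f)):
        raise ValueError("feature map contains non-finite values")
    return f


def _mlp(w: CbamWeights, v: np.ndarray) -> np.ndarray:
    return w.mlp_out @ np.maximum(w.mlp_hidden @ v, 0.0)


def channel_attention(f: np.ndarray, w: CbamWeights) -> np.ndarray:
    """Per-channel gate: sigmoid(MLP(avgpool f) + MLP(maxpool f)), length C."""
    f = _validate_feature(f)
    if f.shape[0] != w.channels:
        raise ValueError(f"feature has {f.shape[0]} channels, weights expect {w.channels}")
    avg = f.mean(axis=(1, 2))
    mx = f.max(axis=(1, 2))
    return _sigmoid(_mlp(w, avg) + _mlp(w, mx))


def spatial_attention(f: np.ndarray, w: CbamWeights) -> np.ndarray:
    """H x W gate: sigmoid(conv7x7([channel-mean; channel-max]) + bias).

    Zero padding of 3 preserves the spatial shape.
    """
    f = _validate_feature(f)
    pooled = np.stack([f.mean(axis=0), f.max(axis=0)])  # 2 x H x W
    # cross-correlation: flip the kernel fed to convolve2d
    out = np.zeros(f.shape[1:], dtype=float)
    for ch in range(2):
        out += convolve2d(pooled[ch], w.spatial_kernel[::-1, ::-1, ch], mode="same")
    return _sigmoid(out + w.spatial_bias)


def cbam_forward(f: np.ndarray, w: CbamWeights) -> np.ndarray:
    """Sequential refinement: f' = f * channel gate, f'' = f' * spatial gate.

    Output shape equals input shape; because both gates lie strictly inside
    (0, 1), every nonzero input entry strictly shrinks in magnitude.
    """
    f = _validate_feature(f)
    gated = f * channel_attention(f, w)[:, None, None]
    return gated * spatial_attention(gated, w)[None, :, :]
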