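"""Convolutional Block Attention Module (CBAM), functional form.

CBAM refines a feature map ``F`` (channels x height x width) in two
sequential stages, each producing multiplicative sigmoid weights:

* channel attention   ``Mc(F) = sigmoid(MLP(AvgPool(F)) + MLP(MaxPool(F)))``
  where the pools are global spatial poolings per channel and the MLP is
  a shared two-layer bottleneck (hidden width C / reduction_ratio,
  ReLU in between, bias only on the output);
* spatial attention   ``Ms(F) = sigmoid(conv_kxk([AvgPool_c(F); MaxPool_c(F)]))``
  where the pools act across channels and the convolution is
  same-padded with a single odd kernel.

``cbam_apply`` computes ``F' = Mc(F) (x) F`` followed by
``F'' = Ms(F') (x) F'``.  Since sigmoid outputs lie strictly in (0, 1),
the block is an elementwise contraction: ``|F''| <= |F|`` everywhere.

This module is pure-forward numpy and is the reference used both
standalone and (in batched, differentiable form) inside the network
module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

__all__ = [
    "CbamConfig",
    "channel_attention",
    "spatial_attention",
    "cbam_apply",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class CbamConfig:
    """CBAM weights and hyper-parameters for a C-channel feature map.

    ``mlp_w1`` (C x C//r) and ``mlp_w2`` (C//r x C) are shared between
    the average- and max-pooled branches; ``mlp_b2`` is the output bias.
    ``conv_w`` (k x k x 2) and ``conv_b`` parameterise the spatial
    convolution over the stacked [average; max] channel-pooled maps.
    """

    reduction_ratio: int = 16
    spatial_kernel: int = 7
    mlp_w1: Optional[np.ndarray] = None
    mlp_w2: Optional[np.ndarray] = None
    mlp_b2: Optional[np.ndarray] = None
    conv_w: Optional[np.ndarray] = None
    conv_b: float = 0.0

    def __post_init__(self) -> None:
        if self.spatial_kernel % 2 == 0 or self.spatial_kernel < 1:
            raise ValueError("spatial_kernel must be an odd positive integer")
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be positive")

    @classmethod
    def initialised(
        cls,
        channels: int,
        reduction_ratio: int = 16,
        spatial_kernel: int = 7,
        rng: Optional[np.random.Generator] = None,
    ) -> "CbamConfig":
        """Random (He-style) initialisation for a given channel count."""
        rng = rng or np.random.default_rng(0)
        hidden = max(1, channels // reduction_ratio)
        k = spatial_kernel
        return cls(
            reduction_ratio=reduction_ratio,
            spatial_kernel=spatial_kernel,
            mlp_w1=rng.normal(0, np.sqrt(2.0 / channels), (channels, hidden)),
            mlp_w2=rng.normal(0, np.sqrt(2.0 / hidden), (hidden, channels)),
            mlp_b2=np.zeros(channels),
            conv_w=rng.normal(0, np.sqrt(2.0 / (2 * k * k)), (k, k, 2)),
            conv_b=0.0,
        )

    def hidden_width(self, channels: int) -> int:
        h = channels // self.reduction_ratio
        if h < 1:
            raise ValueError(
                f"reduction_ratio {self.reduction_ratio} leaves no hidden units "
                f"for {channels} channels"
            )
        return h

    def _materialised(self, channels: int) -> "CbamConfig":
        if self.mlp_w1 is None:
            return CbamConfig.initialised(
                channels, self.reduction_ratio, self.spatial_kernel
            )
        return self


def _mlp(v: np.ndarray, cfg: CbamConfig) -> np.ndarray:
    """Shared bottleneck MLP: ReLU hidden layer, bias only on the output."""
    h = np.maximum(0.0, v @ cfg.mlp_w1)
    return h @ cfg.mlp_w2 + cfg.mlp_b2


def channel_attention(f: np.ndarray, cfg: CbamConfig) -> np.ndarray:
    """Per-channel attention weights, a vector of length C in (0, 1)."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError("feature map must be 3-D (C, H, W)")
    c = f.shape[0]
    cfg = cfg._materialised(c)
    cfg.hidden_width(c)  # validates C / reduction_ratio >= 1
    avg = f.mean(axis=(1, 2))
    mx = f.max(axis=(1, 2))
    return _sigmoid(_mlp(avg, cfg) + _mlp(mx, cfg))


def spatial_attention(f: np.ndarray, cfg: CbamConfig) -> np.ndarray:
    """Per-pixel attention weights, an H x W map in (0, 1)."""
    f = np.asarray(f, dtype=float)
    if f.ndim != 3:
        raise ValueError("feature map must be 3-D (C, H, W)")
    cfg = cfg._materialised(f.shape[0])
    k = cfg.spatial_kernel
    stack = np.stack([f.mean(axis=0), f.max(axis=0)], axis=-1)  # (H, W, 2)
    pad = k // 2
    padded = np.pad(stack, ((pad, pad), (pad, pad), (0, 0)))
    h, w = f.shape[1:]
    windows = np.lib.stride_tricks.sliding_window_view(padded, (k, k), axis=(0, 1))
    # windows: (H, W, 2, k, k); conv_w: (k, k, 2)
    z = np.einsum("hwcij,ijc->hw", windows, cfg.conv_w) + cfg.conv_b
    return _sigmoid(z)


def cbam_apply(f: np.ndarray, cfg: CbamConfig) -> np.ndarray:
    """Sequential CBAM refinement ``F'' = Ms(F') (x) (Mc(F) (x) F)``."""
    f = np.asarray(f, dtype=float)
    cfg = cfg._materialised(f.shape[0])
    mc = channel_attention(f, cfg)
    f1 = mc[:, None, None] * f
    ms = spatial_attention(f1, cfg)
    return ms[None, :, :] * f1
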