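"""Inception-style multi-scale fusion module (MSFM).

Four parallel branches read the same (B, H, W, C) feature map:

1. 1x1 convolution — fine, localized detail;
2. 3x3 convolution — medium-scale context;
3. 5x5 convolution — broad patterns;
4. hybrid max/Hartley-spectral pooling followed by a 1x1 convolution —
   very-large-scale structure and global context (the 1x1 conv also folds
   the doubled channel count of the concatenating hybrid pool back to the
   branch width).

Every convolution is same-padded, stride 1, with bias, and ReLU-activated;
the four branch outputs are concatenated along channels, so the module is
shape-preserving spatially and emits 4x``branch_width`` channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import (Tensor, concat, conv2d, hartley_lowpass_batch,
                      he_uniform, max_pool2d_same)
from .spectral_ops import HybridPoolConfig

__all__ = ["FusionConfig", "init_msfm", "msfm_forward"]

_KERNELS = (1, 3, 5)


@dataclass(frozen=True)
class FusionConfig:
    branch_width: int = 64
    hybrid: HybridPoolConfig = field(default_factory=HybridPoolConfig)

    def __post_init__(self):
        if self.branch_width < 1:
            raise ValueError(f"branch_width must be >= 1, got {self.branch_width}")

    @property
    def out_channels(self) -> int:
        return 4 * self.branch_width


def init_msfm(cfg: FusionConfig, in_channels: int,
              rng: np.random.Generator) -> dict[str, Tensor]:
    w = cfg.branch_width
    params: dict[str, Tensor] = {}
    for i, k in enumerate(_KERNELS, start=1):
        params[f"b{i}_w"] = Tensor(
            he_uniform(rng, (k, k, in_channels, w), k * k * in_channels),
            requires_grad=True)
        params[f"b{i}_b"] = Tensor(np.zeros(w), requires_grad=True)
    pooled_c = 2 * in_channels if cfg.hybrid.combine == "concat" else in_channels
    params["b4_w"] = Tensor(he_uniform(rng, (1, 1, pooled_c, w), pooled_c),
                            requires_grad=True)
    params["b4_b"] = Tensor(np.zeros(w), requires_grad=True)
    return params


def _hybrid_pool_batch(x: Tensor, cfg: HybridPoolConfig) -> Tensor:
    pooled = max_pool2d_same(x, cfg.window)
    smooth = hartley_lowpass_batch(x, cfg.retain_fraction)
    if cfg.combine == "concat":
        return concat([pooled, smooth], axis=3)
    if cfg.combine == "sum":
        return pooled + smooth
    return (pooled + smooth) * 0.5


def msfm_forward(fmap: Tensor, weights: dict[str, Tensor],
                 cfg: FusionConfig) -> Tensor:
    """Apply the four branches and concatenate along channels.

    Output channel layout: [0,w) branch 1, [w,2w) branch 2, [2w,3w) branch 3,
    [3w,4w) branch 4 (hybrid pooling), with w = ``cfg.branch_width``.
    """
    for name, t in weights.items():
        if not np.all(np.isfinite(t.data)):
            raise ValueError(f"non-finite fusion weight {name}")
    b1 = conv2d(fmap, weights["b1_w"], weights["b1_b"]).relu()
    b2 = conv2d(fmap, weights["b2_w"], weights["b2_b"]).relu()
    b3 = conv2d(fmap, weights["b3_w"], weights["b3_b"]).relu()
    pooled = _hybrid_pool_batch(fmap, cfg.hybrid)
    b4 = conv2d(pooled, weights["b4_w"], weights["b4_b"]).relu()
    return concat([b1, b2, b3, b4], axis=3)
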