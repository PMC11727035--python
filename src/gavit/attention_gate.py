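"""Gated control mechanism: channel-, element- and spatial-wise attention.

The gate refines a token sequence X of shape (B, N, D) that carries a known
spatial grid (Hp, Wp) with Hp*Wp = N.  Three independent branches each
produce multiplicative attention weights in (0, 1):

* channel attention — global average- and max-pooling over tokens,
  concatenated and passed through a tanh/sigmoid two-layer MLP, yielding one
  weight per feature channel, broadcast over tokens;
* element attention — an affine map (We, be) per token followed by a
  tanh/sigmoid two-layer MLP, yielding one weight per individual entry;
* spatial attention — tokens reshaped to their (Hp, Wp) grid, channel-wise
  average and max pooled into two planes, concatenated and convolved with a
  7x7 kernel plus sigmoid, yielding one weight per grid position, broadcast
  over channels.

Each branch multiplies its weights into X elementwise; the gate output is
the concatenation of the three attended maps along the feature dimension,
in the fixed order (channel, element, spatial), hence feature width 3D.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._tensor import Tensor, concat, conv2d, glorot_uniform

__all__ = [
    "TokenFeatures",
    "GateParams",
    "channel_attention",
    "element_attention",
    "spatial_attention",
    "gated_combine",
]


@dataclass
class TokenFeatures:
    """A batch of patch-token sequences with their spatial grid.

    values: Tensor of shape (B, N, D); grid: (Hp, Wp) with Hp*Wp == N.
    """

    values: Tensor
    grid: tuple[int, int]

    def __post_init__(self):
        if not isinstance(self.values, Tensor):
            self.values = Tensor(np.asarray(self.values, dtype=np.float64))
        if self.values.ndim != 3:
            raise ValueError(f"expected (B, N, D), got {self.values.shape}")
        hp, wp = self.grid
        if hp * wp != self.values.shape[1]:
            raise ValueError(
                f"grid {self.grid} incompatible with N={self.values.shape[1]}")

    @property
    def dim(self) -> int:
        return self.values.shape[2]


@dataclass
class GateParams:
    """Learnable weights of the three attention branches for feature dim D."""

    dim: int
    reduction: int = 8
    params: dict[str, Tensor] = field(default_factory=dict)

    @classmethod
    def init(cls, dim: int, reduction: int = 8,
             rng: np.random.Generator | None = None) -> "GateParams":
        rng = rng or np.random.default_rng(0)
        h = max(dim // reduction, 1)
        p = {
            # channel branch: pooled avg+max stats (2D) -> h -> D
            "channel_w1": glorot_uniform(rng, (2 * dim, h), 2 * dim, h),
            "channel_b1": np.zeros(h),
            "channel_w2": glorot_uniform(rng, (h, dim), h, dim),
            "channel_b2": np.zeros(dim),
            # element branch: affine (We, be) then D -> D -> D
            "elem_we": glorot_uniform(rng, (dim, dim), dim, dim),
            "elem_be": np.zeros(dim),
            "elem_w1": glorot_uniform(rng, (dim, dim), dim, dim),
            "elem_b1": np.zeros(dim),
            "elem_w2": glorot_uniform(rng, (dim, dim), dim, dim),
            "elem_b2": np.zeros(dim),
            # spatial branch: 7x7 conv, 2 planes in -> 1 out
            "spatial_k": glorot_uniform(rng, (7, 7, 2, 1), 7 * 7 * 2, 1),
            "spatial_b": np.zeros(1),
        }
        return cls(dim, reduction,
                   {k: Tensor(v, requires_grad=True) for k, v in p.items()})

    def zero_branch(self, branch: str) -> None:
        """Zero every weight of one branch (channel/element/spatial)."""
        prefix = {"channel": "channel_", "element": "elem_", "spatial": "spatial_"}[branch]
        for k, t in self.params.items():
            if k.startswith(prefix):
                t.data[...] = 0.0


def _check_weights(values: Tensor, branch: str) -> None:
    if np.any(np.isnan(values.data)):
        raise FloatingPointError(f"NaN attention weights in {branch} branch")


def channel_attention(x: TokenFeatures, params: GateParams) -> TokenFeatures:
    """Scale each feature channel by a pooled-statistics attention weight."""
    p = params.params
    v = x.values
    avg = v.mean(axis=1)          # (B, D)
    mx = v.max(axis=1)            # (B, D)
    stats = concat([avg, mx], axis=1)
    hidden = (stats @ p["channel_w1"] + p["channel_b1"]).tanh()
    weights = (hidden @ p["channel_w2"] + p["channel_b2"]).sigmoid()  # (B, D)
    _check_weights(weights, "channel")
    B, D = weights.shape
    out = v * weights.reshape(B, 1, D)
    return TokenFeatures(out, x.grid)


def element_attention(x: TokenFeatures, params: GateParams) -> TokenFeatures:
    """Scale every individual entry by its own attention weight."""
    p = params.params
    v = x.values
    u = v @ p["elem_we"] + p["elem_be"]
    hidden = (u @ p["elem_w1"] + p["elem_b1"]).tanh()
    weights = (hidden @ p["elem_w2"] + p["elem_b2"]).sigmoid()  # (B, N, D)
    _check_weights(weights, "element")
    return TokenFeatures(v * weights, x.grid)


def spatial_attention(x: TokenFeatures, params: GateParams) -> TokenFeatures:
    """Scale each grid position by a 7x7-convolution attention weight."""
    p = params.params
    hp, wp = x.grid
    v = x.values
    B, N, D = v.shape
    grid = v.reshape(B, hp, wp, D)
    avg = grid.mean(axis=3, keepdims=True)
    mx = grid.max(axis=3, keepdims=True)
    planes = concat([avg, mx], axis=3)                      # (B, Hp, Wp, 2)
    conv = conv2d(planes, p["spatial_k"], p["spatial_b"])   # (B, Hp, Wp, 1)
    weights = conv.sigmoid()
    _check_weights(weights, "spatial")
    out = (grid * weights).reshape(B, N, D)
    return TokenFeatures(out, x.grid)


def gated_combine(x: TokenFeatures, params: GateParams) -> TokenFeatures:
    """Run the three branches on the same input and concatenate the results.

    Output feature dimension is exactly 3x the input's, ordered
    (channel, element, spatial).
    """
    ch = channel_attention(x, params)
    el = element_attention(x, params)
    sp = spatial_attention(x, params)
    out = concat([ch.values, el.values, sp.values], axis=2)
    return TokenFeatures(out, x.grid)
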