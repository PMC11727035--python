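"""Hartley-domain spectral pooling and hybrid max/spectral pooling.

The discrete Hartley transform (DHT) of an M×N plane is

    H(u, v) = sum_{x,y} f(x, y) * cas(2*pi*(u*x/M + v*y/N)),   cas t = cos t + sin t.

It is real-to-real and self-inverse up to a 1/(M*N) scale, which makes it a
cheap vehicle for frequency-domain filtering of feature maps: low-pass
filtering in the Hartley domain keeps global spatial structure while
discarding high-frequency content.  Hybrid pooling pairs that spectral
low-pass with an ordinary sliding-window max pool and combines the two
(by default concatenating along channels), so downstream convolutions see
both the "sharpest local evidence" and the "smoothed global layout" view
of the same feature map.

All functions here are plain-NumPy and shape-preserving; the
differentiable batched counterparts used inside the model live in
:mod:`gavit._tensor` and share this module's numeric kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "HybridPoolConfig",
    "dht2",
    "hartley_lowpass",
    "max_pool_same",
    "hybrid_pool",
]


@dataclass(frozen=True)
class HybridPoolConfig:
    """Parameters of the hybrid max/spectral pooling stage.

    window:
        Odd side of the stride-1, same-padded max-pool window.
    retain_fraction:
        Fraction rho in (0, 1] of the (centered) frequency band retained by
        the Hartley low-pass; rho = 1 keeps every coefficient.
    combine:
        How the two pooled maps are merged: ``"concat"`` (channel
        concatenation, the default — output has 2C channels), ``"sum"`` or
        ``"mean"`` (elementwise, output keeps C channels).
    """

    window: int = 3
    retain_fraction: float = 0.5
    combine: str = "concat"

    def __post_init__(self):
        if self.window < 1 or self.window % 2 != 1:
            raise ValueError(f"window must be odd and >= 1, got {self.window}")
        if not (0.0 < self.retain_fraction <= 1.0):
            raise ValueError(
                f"retain_fraction must be in (0, 1], got {self.retain_fraction}")
        if self.combine not in ("concat", "sum", "mean"):
            raise ValueError(f"unknown combine rule {self.combine!r}")


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(arr))[0])
        raise ValueError(f"{name} contains a non-finite value at index {idx}")


def dht2(plane: np.ndarray) -> np.ndarray:
    """2-D discrete Hartley transform of a real plane.

    Computed through the FFT as Re(F) - Im(F), which equals the direct
    cas-kernel sum.  Self-inverse up to 1/(M*N): ``dht2(dht2(f)) == M*N*f``.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError(f"dht2 expects a 2-D plane, got shape {plane.shape}")
    _check_finite(plane, "dht2 input")
    F = np.fft.fft2(plane)
    return F.real - F.imag


def _lowpass_mask(M: int, N: int, rho: float) -> np.ndarray:
    """Boolean retain-mask in natural (DC at [0,0]) frequency order.

    The "low-frequency block" is defined in the DC-centered view: shift the
    DC coefficient to (M//2, N//2), keep the centered block of side
    ceil(rho*M) x ceil(rho*N) (even block sides place the extra row/column
    on the low-index side), then shift back.
    """
    h = int(np.ceil(rho * M))
    w = int(np.ceil(rho * N))
    cM, cN = M // 2, N // 2
    mask = np.zeros((M, N), dtype=bool)
    r0, c0 = cM - h // 2, cN - w // 2
    mask[r0:r0 + h, c0:c0 + w] = True
    return np.roll(mask, (-cM, -cN), axis=(0, 1))


def _lowpass_apply_batch(x: np.ndarray, rho: float) -> np.ndarray:
    """Hartley low-pass applied over axes (1, 2) of a (B, H, W, C) array."""
    if not (0.0 < rho <= 1.0):
        raise ValueError(f"retain fraction must be in (0, 1], got {rho}")
    H, W = x.shape[1], x.shape[2]
    mask = _lowpass_mask(H, W, rho)[None, :, :, None]
    F = np.fft.fft2(x, axes=(1, 2))
    coeff = (F.real - F.imag) * mask
    F2 = np.fft.fft2(coeff, axes=(1, 2))
    return (F2.real - F2.imag) / (H * W)


def hartley_lowpass(plane: np.ndarray, rho: float) -> np.ndarray:
    """Shape-preserving spectral low-pass of a 2-D plane.

    Forward DHT, zero every coefficient outside the centered low-frequency
    block of side ``ceil(rho*M) x ceil(rho*N)``, inverse DHT.  ``rho = 1``
    is the identity; a constant plane is invariant for any ``rho`` (only
    its DC coefficient is nonzero and DC is always retained).  The filter
    is linear and idempotent.
    """
    plane = np.asarray(plane, dtype=np.float64)
    if plane.ndim != 2:
        raise ValueError(f"hartley_lowpass expects a 2-D plane, got {plane.shape}")
    _check_finite(plane, "hartley_lowpass input")
    return _lowpass_apply_batch(plane[None, :, :, None], rho)[0, :, :, 0]


def max_pool_same(fmap: np.ndarray, window: int) -> np.ndarray:
    """Stride-1 sliding-window maximum with same padding.

    Accepts an (H, W) plane or (H, W, C) stack; borders use -inf padding so
    ``out[i, j] >= in[i, j]`` everywhere and a window of 1 is the identity.
    """
    if window < 1 or window % 2 != 1:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    fmap = np.asarray(fmap, dtype=np.float64)
    squeeze = fmap.ndim == 2
    if squeeze:
        fmap = fmap[:, :, None]
    if fmap.ndim != 3:
        raise ValueError(f"expected (H, W) or (H, W, C), got {fmap.shape}")
    _check_finite(fmap, "max_pool_same input")
    if window == 1:
        out = fmap.copy()
    else:
        p = window // 2
        xp = np.pad(fmap, ((p, p), (p, p), (0, 0)), constant_values=-np.inf)
        win = sliding_window_view(xp, (window, window), axis=(0, 1))
        out = win.max(axis=(-2, -1))
    return out[:, :, 0] if squeeze else out


def hybrid_pool(fmap: np.ndarray, cfg: HybridPoolConfig) -> np.ndarray:
    """Combine max pooling and Hartley spectral pooling of a feature map.

    ``fmap`` is (H, W, C).  With ``combine="concat"`` the result is
    (H, W, 2C): channels [0, C) hold the max-pooled map and [C, 2C) the
    spectrally low-passed map.  ``"sum"``/``"mean"`` merge elementwise and
    keep C channels.  Any channel-count reconciliation (the 1x1 convolution
    of the fusion module's pooling branch) happens downstream, not here.
    """
    fmap = np.asarray(fmap, dtype=np.float64)
    if fmap.ndim != 3:
        raise ValueError(f"hybrid_pool expects (H, W, C), got {fmap.shape}")
    pooled = max_pool_same(fmap, cfg.window)
    smooth = _lowpass_apply_batch(fmap[None], cfg.retain_fraction)[0]
    if cfg.combine == "concat":
        return np.concatenate([pooled, smooth], axis=-1)
    if cfg.combine == "sum":
        return pooled + smooth
    return 0.5 * (pooled + smooth)
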