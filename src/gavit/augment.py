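"""Pixel normalization, CutMix and RandAugment for radiograph-like images.

Images are float arrays in [0, 1], shaped (H, W) or (H, W, C); batches add a
leading axis.  CutMix pastes a rectangle from a partner image and mixes the
one-hot labels by exact pixel-area fraction; RandAugment applies N randomly
chosen transforms from a grayscale-safe pool at a shared magnitude M on a
0..30 scale.  All randomness flows through an explicit
``numpy.random.Generator`` so a fixed seed reproduces outputs bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CutMixSpec",
    "RandAugmentSpec",
    "normalize",
    "apply_cutmix_box",
    "cutmix",
    "randaugment",
    "RANDAUGMENT_POOL",
]


@dataclass(frozen=True)
class CutMixSpec:
    alpha: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError(f"alpha must be > 0, got {self.alpha}")


# color-specific ops are omitted: inputs are replicated-grayscale radiographs
RANDAUGMENT_POOL = ("rotate", "translate_x", "translate_y", "shear_x",
                    "shear_y", "contrast", "brightness", "sharpness",
                    "posterize", "equalize", "autocontrast")


@dataclass(frozen=True)
class RandAugmentSpec:
    num_ops: int = 2
    magnitude: int = 9
    ops: tuple[str, ...] = RANDAUGMENT_POOL

    def __post_init__(self):
        if self.num_ops < 1:
            raise ValueError(f"num_ops must be >= 1, got {self.num_ops}")
        if not (0 <= self.magnitude <= 30):
            raise ValueError(f"magnitude must be in [0, 30], got {self.magnitude}")
        unknown = set(self.ops) - set(RANDAUGMENT_POOL)
        if unknown:
            raise ValueError(f"unknown ops in pool: {sorted(unknown)}")


def normalize(image: np.ndarray) -> np.ndarray:
    """Map 8-bit pixel values 0..255 to [0, 1] by dividing by 255."""
    arr = np.asarray(image)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(
            f"pixel values must lie in [0, 255]; got [{arr.min()}, {arr.max()}]")
    return arr.astype(np.float64) / 255.0


# ---------------------------------------------------------------------
# CutMix
# ---------------------------------------------------------------------

def apply_cutmix_box(image_i: np.ndarray, image_j: np.ndarray,
                     label_i: np.ndarray, label_j: np.ndarray,
                     box: tuple[int, int, int, int]):
    """Paste ``image_j``'s box into ``image_i`` and area-mix the labels.

    ``box`` is (y1, y2, x1, x2), half-open.  The mixed label is
    ``lam * label_i + (1 - lam) * label_j`` with
    ``lam = 1 - box_area / (H * W)`` — the exact pixel-area fraction.
    """
    y1, y2, x1, x2 = box
    H, W = image_i.shape[0], image_i.shape[1]
    mixed = image_i.copy()
    mixed[y1:y2, x1:x2, ...] = image_j[y1:y2, x1:x2, ...]
    lam = 1.0 - (y2 - y1) * (x2 - x1) / float(H * W)
    return mixed, lam * np.asarray(label_i, dtype=np.float64) \
        + (1.0 - lam) * np.asarray(label_j, dtype=np.float64)


def _sample_box(H: int, W: int, lam: float,
                rng: np.random.Generator) -> tuple[int, int, int, int]:
    ratio = np.sqrt(1.0 - lam)
    rh, rw = int(np.round(H * ratio)), int(np.round(W * ratio))
    cy, cx = int(rng.integers(H)), int(rng.integers(W))
    y1, y2 = np.clip([cy - rh // 2, cy - rh // 2 + rh], 0, H)
    x1, x2 = np.clip([cx - rw // 2, cx - rw // 2 + rw], 0, W)
    return int(y1), int(y2), int(x1), int(x2)


def cutmix(images: np.ndarray, labels: np.ndarray, spec: CutMixSpec,
           rng: np.random.Generator | None = None):
    """CutMix a batch: each image receives a box from a permuted partner.

    ``labels`` must be one-hot (B, K).  Returns (mixed images, mixed labels);
    mixed labels are convex combinations whose weights equal the pixel-area
    fractions of the two sources exactly.
    """
    images = np.asarray(images, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if images.shape[0] < 2:
        raise ValueError("cutmix needs a batch of at least 2 images")
    onehot = (labels >= 0).all() and np.allclose(labels.sum(axis=1), 1.0) \
        and np.all((labels == 0) | (labels == 1))
    if labels.ndim != 2 or not onehot:
        raise ValueError("labels must be one-hot rows")
    rng = rng or np.random.default_rng(spec.seed)
    perm = rng.permutation(images.shape[0])
    H, W = images.shape[1], images.shape[2]
    out_x = np.empty_like(images)
    out_y = np.empty_like(labels)
    for i, j in enumerate(perm):
        lam = rng.beta(spec.alpha, spec.alpha)
        box = _sample_box(H, W, lam, rng)
        out_x[i], out_y[i] = apply_cutmix_box(
            images[i], images[j], labels[i], labels[j], box)
    return out_x, out_y


# ---------------------------------------------------------------------
# RandAugment
# ---------------------------------------------------------------------

def _geometric(image: np.ndarray, matrix: np.ndarray,
               offset: np.ndarray) -> np.ndarray:
    """Affine warp about the image center, bilinear, zero fill."""
    if image.ndim == 3:
        return np.stack([_geometric(image[..., c], matrix, offset)
                         for c in range(image.shape[-1])], axis=-1)
    return ndimage.affine_transform(image, matrix, offset=offset, order=1,
                                    mode="constant", cval=0.0)


def _rotate(image, level, sign):
    angle = sign * 30.0 * level
    if angle == 0.0:
        return image.copy()
    out = ndimage.rotate(image, angle, axes=(1, 0), reshape=False, order=1,
                         mode="constant", cval=0.0)
    return out


def _translate(image, level, sign, axis):
    shift_px = sign * 0.3 * image.shape[axis] * level
    if shift_px == 0.0:
        return image.copy()
    shift = [0.0] * image.ndim
    shift[axis] = shift_px
    return ndimage.shift(image, shift, order=1, mode="constant", cval=0.0)


def _shear(image, level, sign, axis):
    s = sign * 0.3 * level
    if s == 0.0:
        return image.copy()
    matrix = np.eye(2)
    matrix[axis, 1 - axis] = s
    center = (np.array(image.shape[:2]) - 1) / 2.0
    offset = center - matrix @ center
    return _geometric(image, matrix, offset)


def _blend_factor(level, sign):
    return 1.0 + sign * 0.9 * level


def _contrast(image, level, sign):
    f = _blend_factor(level, sign)
    mean = image.mean()
    return mean + (image - mean) * f


def _brightness(image, level, sign):
    return image * _blend_factor(level, sign)


_SMOOTH = np.array([[1, 1, 1], [1, 5, 1], [1, 1, 1]], dtype=np.float64) / 13.0


def _sharpness(image, level, sign):
    f = _blend_factor(level, sign)
    if image.ndim == 3:
        blur = np.stack([ndimage.convolve(image[..., c], _SMOOTH, mode="nearest")
                         for c in range(image.shape[-1])], axis=-1)
    else:
        blur = ndimage.convolve(image, _SMOOTH, mode="nearest")
    return blur + (image - blur) * f


def _posterize(image, level, sign):
    bits = 8 - int(np.round(4 * level))
    levels = 2 ** bits
    return np.floor(image * (levels - 1e-9)) / max(levels - 1, 1)


def _equalize(image, level, sign):
    flat = image.reshape(-1)
    hist, edges = np.histogram(flat, bins=256, range=(0.0, 1.0))
    cdf = hist.cumsum().astype(np.float64)
    if cdf[-1] == 0:
        return image.copy()
    cdf = (cdf - cdf.min()) / max(cdf[-1] - cdf.min(), 1.0)
    idx = np.clip((flat * 255).astype(int), 0, 255)
    return cdf[idx].reshape(image.shape)


def _autocontrast(image, level, sign):
    lo, hi = image.min(), image.max()
    if hi <= lo:
        return image.copy()
    return (image - lo) / (hi - lo)


_OPS = {
    "rotate": lambda im, lv, sg: _rotate(im, lv, sg),
    "translate_x": lambda im, lv, sg: _translate(im, lv, sg, axis=1),
    "translate_y": lambda im, lv, sg: _translate(im, lv, sg, axis=0),
    "shear_x": lambda im, lv, sg: _shear(im, lv, sg, axis=1),
    "shear_y": lambda im, lv, sg: _shear(im, lv, sg, axis=0),
    "contrast": _contrast,
    "brightness": _brightness,
    "sharpness": _sharpness,
    "posterize": _posterize,
    "equalize": _equalize,
    "autocontrast": _autocontrast,
}

# ops whose strength scales with the magnitude (identity at M = 0)
MAGNITUDE_SCALED_OPS = ("rotate", "translate_x", "translate_y", "shear_x",
                        "shear_y", "contrast", "brightness", "sharpness")


def randaugment(image: np.ndarray, spec: RandAugmentSpec,
                rng: np.random.Generator) -> np.ndarray:
    """Apply N uniformly chosen transforms at magnitude M; clip to [0, 1]."""
    image = np.asarray(image, dtype=np.float64)
    if image.min() < 0 or image.max() > 1:
        raise ValueError("randaugment expects an image in [0, 1]")
    level = spec.magnitude / 30.0
    for _ in range(spec.num_ops):
        name = spec.ops[int(rng.integers(len(spec.ops)))]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        image = _OPS[name](image, level, sign)
        image = np.clip(image, 0.0, 1.0)
    return image
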