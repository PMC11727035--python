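"""Seeded generator of 4-class chest-radiograph-like images.

The four class profiles differ in both spatial layout and frequency
content, so every pathway of the classifier has signal to find:

* ``clear_field`` — the bare anatomical template: two bright elliptical
  "lung fields" on a dark thorax with a border vignette;
* ``focal_opacity`` — adds a few bright Gaussian blobs inside the lung
  ellipses (localized, low-frequency structure);
* ``diffuse_haze`` — adds a smooth random low-frequency intensity field
  over the lung region (global, low-frequency);
* ``nodular_speckle`` — adds sparse bright single-pixel dots (fine,
  high-frequency texture).

Images are 8-bit grayscale PNGs on disk (replicated to 3 channels at load
time); generation is fully deterministic given the spec and its seed.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "CLASS_NAMES",
    "SynthSpec",
    "render_class_image",
    "generate_arrays",
    "generate_dataset",
    "load_dataset",
    "to_model_input",
]

CLASS_NAMES = ("clear_field", "focal_opacity", "diffuse_haze", "nodular_speckle")


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions of the synthetic dataset.

    Amplitudes are in 8-bit gray levels; fractions are relative to the
    image side.  ``noise_sd`` is additive Gaussian pixel noise.
    """

    n_per_class: int = 100
    image_side: int = 224
    noise_sd: float = 8.0
    blob_count: int = 4
    blob_sigma_frac: float = 0.06
    blob_amp: float = 70.0
    haze_amp: float = 45.0
    haze_cells: int = 6
    speckle_density: float = 0.01
    speckle_amp: float = 90.0
    speckle_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_side < 16:
            raise ValueError("image_side must be >= 16")


_TEMPLATE_CACHE: dict[int, np.ndarray] = {}

# lung-field ellipses: (center_y, center_x, semi_y, semi_x) as side fractions
_ELLIPSES = ((0.55, 0.32, 0.30, 0.17), (0.55, 0.68, 0.30, 0.17))


def _lung_mask(side: int) -> np.ndarray:
    yy, xx = np.mgrid[0:side, 0:side] / (side - 1)
    mask = np.zeros((side, side))
    for cy, cx, sy, sx in _ELLIPSES:
        r = np.sqrt(((yy - cy) / sy) ** 2 + ((xx - cx) / sx) ** 2)
        mask = np.maximum(mask, np.clip(1.25 - r, 0.0, 1.0))
    return np.minimum(mask, 1.0)


def _template(side: int) -> np.ndarray:
    """Deterministic background: dark thorax, lung fields, vignette."""
    if side not in _TEMPLATE_CACHE:
        base = 25.0 + 100.0 * _lung_mask(side)
        w = 0.7 + 0.3 * np.hanning(side)
        _TEMPLATE_CACHE[side] = base * np.outer(w, w)
    return _TEMPLATE_CACHE[side]


def _sample_in_lungs(rng: np.random.Generator, side: int) -> tuple[float, float]:
    cy, cx, sy, sx = _ELLIPSES[int(rng.integers(2))]
    for _ in range(100):
        y = rng.normal(cy, sy * 0.5)
        x = rng.normal(cx, sx * 0.5)
        if ((y - cy) / sy) ** 2 + ((x - cx) / sx) ** 2 <= 1.0:
            return y * (side - 1), x * (side - 1)
    return cy * (side - 1), cx * (side - 1)


def render_class_image(class_id: int, spec: SynthSpec,
                       rng: np.random.Generator) -> np.ndarray:
    """One uint8 (side, side) image of the given class profile."""
    if not 0 <= class_id <= 3:
        raise ValueError(f"class_id must be in 0..3, got {class_id}")
    side = spec.image_side
    img = _template(side).copy()
    lungs = _lung_mask(side)
    yy, xx = np.mgrid[0:side, 0:side]

    if class_id == 1:  # focal opacity: Gaussian blobs inside the lung fields
        sigma = spec.blob_sigma_frac * side
        for _ in range(spec.blob_count):
            by, bx = _sample_in_lungs(rng, side)
            img += spec.blob_amp * np.exp(
                -((yy - by) ** 2 + (xx - bx) ** 2) / (2.0 * sigma ** 2))
    elif class_id == 2:  # diffuse haze: smooth random low-frequency field
        coarse = rng.random((spec.haze_cells, spec.haze_cells))
        from scipy.ndimage import zoom
        field = zoom(coarse, side / spec.haze_cells, order=3)[:side, :side]
        img += spec.haze_amp * field * lungs
    elif class_id == 3:  # nodular speckle: sparse dots a couple of pixels wide
        from scipy.ndimage import gaussian_filter
        dots = (rng.random((side, side)) < spec.speckle_density).astype(float)
        s = spec.speckle_sigma
        field = gaussian_filter(dots, s) * (2.0 * np.pi * s ** 2)
        img += spec.speckle_amp * field * (0.3 + 0.7 * lungs)

    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _image_rng(spec: SynthSpec, class_id: int, idx: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, class_id, idx])


def generate_arrays(spec: SynthSpec):
    """In-memory dataset: (images uint8 (N, side, side), labels int (N,)).

    Samples are ordered class-major; each image's random stream is derived
    from (seed, class, index), so any subset is reproducible independently.
    """
    images, labels = [], []
    for c in range(4):
        for i in range(spec.n_per_class):
            images.append(render_class_image(c, spec, _image_rng(spec, c, i)))
            labels.append(c)
    return np.stack(images), np.array(labels)


def generate_dataset(spec: SynthSpec, out_dir) -> dict:
    """Write the dataset as PNGs in class subdirectories plus metadata.

    Layout: ``<out>/<class_name>/<idx>.png``, a ``labels.csv`` with header
    ``filename,label`` and a ``manifest.json`` echoing the spec.  Returns
    the manifest.  Regeneration with the same spec is byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for c, name in enumerate(CLASS_NAMES):
        cdir = out / name
        cdir.mkdir(exist_ok=True)
        for i in range(spec.n_per_class):
            img = render_class_image(c, spec, _image_rng(spec, c, i))
            fname = f"{name}/{i:04d}.png"
            Image.fromarray(img, mode="L").save(out / fname)
            rows.append((fname, name))
    with open(out / "labels.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        writer.writerows(rows)
    manifest = {"spec": asdict(spec), "seed": spec.seed,
                "classes": list(CLASS_NAMES),
                "counts": {name: spec.n_per_class for name in CLASS_NAMES},
                "total": 4 * spec.n_per_class}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def load_dataset(data_dir):
    """Read an image-folder dataset back as (images uint8, labels, names)."""
    root = Path(data_dir)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class subdirectories under {root}")
    images, labels = [], []
    names = [d.name for d in class_dirs]
    for c, d in enumerate(class_dirs):
        for f in sorted(d.glob("*.png")) + sorted(d.glob("*.jpg")):
            images.append(np.asarray(Image.open(f).convert("L")))
            labels.append(c)
    return np.stack(images), np.array(labels), names


def to_model_input(images: np.ndarray) -> np.ndarray:
    """uint8 grayscale (N, H, W) → float (N, H, W, 3) in [0, 1]."""
    x = images.astype(np.float64) / 255.0
    return np.repeat(x[..., None], 3, axis=-1)
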