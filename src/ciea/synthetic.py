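"""Synthetic two-class chest-radiograph-like image generator.

Real chest X-ray collections of the kind used to train pneumonia
classifiers are rarely redistributable, so this module produces a fully
seeded stand-in with the same gross statistical structure: a dark
background, two bright elliptical "lung fields", and — for the positive
class — a handful of diffuse, Gaussian-shaped opacities placed inside
the lung fields, all corrupted by additive Gaussian noise.

The generator is deliberately simple (no ribs, mediastinum or scatter
physics); its only job is to give every downstream stage — curvelet
enhancement, attention CNN, pipeline — a reproducible, separable binary
classification problem.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

__all__ = [
    "SynthConfig",
    "LabeledImage",
    "generate_dataset",
    "write_dataset",
    "read_dataset",
    "lung_field_mask",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the synthetic dataset.

    Attributes
    ----------
    image_size
        Side length in pixels (images are square). Must be >= 32 so the
        curvelet transform downstream has room for at least two scales.
    n_images
        Total number of images across both classes.
    opacity_count_range
        Inclusive ``(lo, hi)`` range for the number of opacities added
        to each positive-class image.
    opacity_radius_range
        Inclusive ``(lo, hi)`` range, in pixels, for the Gaussian radius
        of each opacity.
    opacity_intensity
        Peak added intensity of one opacity, in (0, 1].
    noise_sigma
        Standard deviation of the additive Gaussian pixel noise.
    class_balance
        Fraction of positive (pneumonia) images, in (0, 1).
    seed
        Seed of the single RNG stream that drives label order, per-image
        geometry jitter, opacity placement and noise — in that order.
    """

    image_size: int = 64
    n_images: int = 100
    opacity_count_range: Tuple[int, int] = (2, 5)
    opacity_radius_range: Tuple[float, float] = (3.0, 8.0)
    opacity_intensity: float = 0.4
    noise_sigma: float = 0.03
    class_balance: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size < 32:
            raise ConfigurationError("image_size must be >= 32")
        if self.n_images < 1:
            raise ConfigurationError("n_images must be positive")
        if not (0.0 < self.class_balance < 1.0):
            raise ConfigurationError("class_balance must lie in (0, 1)")
        n_pos = int(round(self.class_balance * self.n_images))
        if n_pos < 1 or self.n_images - n_pos < 1:
            raise ConfigurationError(
                "class_balance * n_images must leave at least one image per class"
            )
        lo, hi = self.opacity_count_range
        if lo > hi or lo < 0:
            raise ConfigurationError("opacity_count_range is empty or negative")
        rlo, rhi = self.opacity_radius_range
        if rlo > rhi or rlo <= 0:
            raise ConfigurationError("opacity_radius_range is empty or non-positive")
        if not (0.0 < self.opacity_intensity <= 1.0):
            raise ConfigurationError("opacity_intensity must lie in (0, 1]")
        if self.noise_sigma < 0:
            raise ConfigurationError("noise_sigma must be non-negative")


@dataclass
class LabeledImage:
    """A grayscale image with its binary pneumonia label."""

    pixels: np.ndarray  # 2-D float array in [0, 1]
    label: int  # 0 = no pneumonia, 1 = pneumonia
    id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")


# Fixed relative geometry of the two lung fields: (cy, cx, ry, rx) as
# fractions of the image side.
_LUNG_GEOMETRY = (
    (0.52, 0.30, 0.30, 0.16),
    (0.52, 0.70, 0.30, 0.16),
)
_BACKGROUND = 0.12
_LUNG_AMPLITUDE = 0.38
_EDGE_SHARPNESS = 12.0  # sigmoid slope of the lung-field boundary
_JITTER = 0.02  # relative jitter of centres and radii per image


def _ellipse_field(n: int, geometry, sharp: float = _EDGE_SHARPNESS) -> np.ndarray:
    """Smooth indicator (values in [0,1]) of the union of two ellipses."""
    yy, xx = np.mgrid[0:n, 0:n] / float(n)
    field = np.zeros((n, n))
    for cy, cx, ry, rx in geometry:
        r2 = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2
        field = np.maximum(field, 1.0 / (1.0 + np.exp(sharp * (np.sqrt(r2) - 1.0))))
    return field


def lung_field_mask(image_size: int, margin: float = 0.0) -> np.ndarray:
    """Boolean interior mask of the canonical (un-jittered) lung fields.

    ``margin`` shrinks the ellipses by the given relative amount, which
    is useful when a strictly interior region is wanted.
    """
    n = image_size
    yy, xx = np.mgrid[0:n, 0:n] / float(n)
    mask = np.zeros((n, n), dtype=bool)
    for cy, cx, ry, rx in _LUNG_GEOMETRY:
        r2 = ((yy - cy) / (ry * (1 - margin))) ** 2 + ((xx - cx) / (rx * (1 - margin))) ** 2
        mask |= r2 < 1.0
    return mask


def _jittered_geometry(rng: np.random.Generator):
    out = []
    for cy, cx, ry, rx in _LUNG_GEOMETRY:
        jit = rng.uniform(-_JITTER, _JITTER, size=4)
        out.append((cy + jit[0], cx + jit[1], ry * (1 + jit[2]), rx * (1 + jit[3])))
    return out


def generate_dataset(config: SynthConfig) -> List[LabeledImage]:
    """Generate the full synthetic dataset described by ``config``.

    The RNG stream is consumed in a fixed, documented order (label
    shuffle; then per image: geometry jitter, opacities if positive,
    noise field), so identical configs produce bit-identical output on
    any platform.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_images
    n_pos = int(round(config.class_balance * n))
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)

    size = config.image_size
    images: List[LabeledImage] = []
    for i, label in enumerate(labels):
        geometry = _jittered_geometry(rng)
        img = _BACKGROUND + _LUNG_AMPLITUDE * _ellipse_field(size, geometry)
        if label == 1:
            img = img + _opacities(size, geometry, config, rng)
        if config.noise_sigma > 0:
            img = img + rng.normal(0.0, config.noise_sigma, size=(size, size))
        images.append(
            LabeledImage(np.clip(img, 0.0, 1.0), int(label), id=f"synth-{i:05d}")
        )
    return images


def _opacities(size, geometry, config: SynthConfig, rng) -> np.ndarray:
    """Sum of diffuse Gaussian bumps placed inside the jittered lung fields."""
    lo, hi = config.opacity_count_range
    k = int(rng.integers(lo, hi + 1))
    yy, xx = np.mgrid[0:size, 0:size].astype(float)
    bumps = np.zeros((size, size))
    for _ in range(k):
        cy, cx, ry, rx = geometry[int(rng.integers(0, len(geometry)))]
        # rejection-free placement: sample in the ellipse via polar coords
        ang = rng.uniform(0.0, 2 * np.pi)
        rad = np.sqrt(rng.uniform(0.0, 1.0)) * 0.8
        py = (cy + rad * np.sin(ang) * ry) * size
        px = (cx + rad * np.cos(ang) * rx) * size
        sigma = rng.uniform(*config.opacity_radius_range) / 2.0
        d2 = (yy - py) ** 2 + (xx - px) ** 2
        bumps += config.opacity_intensity * np.exp(-d2 / (2.0 * sigma**2))
    return bumps


def write_dataset(images: Sequence[LabeledImage], directory: str) -> str:
    """Write images as 8-bit grayscale PNGs plus a CSV manifest.

    Images go to ``<directory>/<label>/<id>.png``; the manifest
    ``<directory>/manifest.csv`` has the header ``id,label,path`` with
    paths relative to ``directory``. Returns the manifest path.
    """
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    manifest = os.path.join(directory, "manifest.csv")
    rows = []
    for im in images:
        sub = os.path.join(directory, str(im.label))
        os.makedirs(sub, exist_ok=True)
        rel = os.path.join(str(im.label), f"{im.id}.png")
        data = np.round(np.clip(im.pixels, 0, 1) * 255).astype(np.uint8)
        iio.imwrite(os.path.join(directory, rel), data)
        rows.append((im.id, im.label, rel))
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "label", "path"])
        writer.writerows(rows)
    return manifest


def read_dataset(manifest: str) -> List[LabeledImage]:
    """Read a dataset previously written by :func:`write_dataset`."""
    import imageio.v3 as iio

    root = os.path.dirname(os.path.abspath(manifest))
    images: List[LabeledImage] = []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            data = iio.imread(os.path.join(root, row["path"]))
            images.append(
                LabeledImage(np.asarray(data, dtype=float) / 255.0,
                             int(row["label"]), id=row["id"])
            )
    return images
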