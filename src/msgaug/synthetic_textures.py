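"""Seeded generator of class-separable synthetic RGB texture patches.

Stands in for stained-tissue patch collections so that the whole
augmentation pipeline — per-class generative training, confidence
filtering, classification — can be exercised end to end on a laptop CPU
with no external download.  Each class is a coloured canvas scattered with
Poisson-distributed coloured disks plus Gaussian pixel noise: the minimum
structure for which class-conditional generation and classification are
both non-degenerate.  No histological realism is attempted.

Class 0 emulates a bright, near-uniform background class and class 1 a
pale, sparse class (the two visually extreme tissue categories in public
colorectal patch data); further classes sweep a colour wheel with varying
disk density.
"""

from __future__ import annotations

import colorsys
import dataclasses

import numpy as np

from .data import LabeledImageSet

__all__ = [
    "TextureClassSpec",
    "SyntheticDatasetConfig",
    "make_class_specs",
    "render_image",
    "generate_dataset",
]


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclasses.dataclass(frozen=True)
class TextureClassSpec:
    """Rendering parameters of one synthetic texture class.

    Colours are RGB triples in [0, 1]; ``blob_density`` is the Poisson mean
    number of disks per image; ``noise_sd`` is the pixel-noise standard
    deviation on the [-1, 1] intensity scale.
    """

    class_id: int
    base_color: tuple[float, float, float]
    blob_density: float
    blob_radius_range: tuple[float, float]
    blob_color: tuple[float, float, float]
    noise_sd: float

    def __post_init__(self):
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        if self.blob_density < 0:
            raise ValueError("blob_density must be >= 0")
        lo, hi = self.blob_radius_range
        if lo > hi:
            raise ValueError("blob_radius_range must satisfy min <= max")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c in (*self.base_color, *self.blob_color):
            if not 0.0 <= c <= 1.0:
                raise ValueError("colours must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class SyntheticDatasetConfig:
    n_classes: int = 9
    per_class_count: int = 100
    resolution: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.per_class_count < 1:
            raise ValueError("per_class_count must be positive")
        if not _is_power_of_two(self.resolution) or self.resolution < 4:
            raise ValueError(
                f"resolution must be a power of two >= 4, got {self.resolution}")


def make_class_specs(n_classes: int, seed: int) -> list[TextureClassSpec]:
    """Build ``n_classes`` pairwise-distinct texture specs, deterministic in seed.

    Class 0 is a near-uniform bright class, class 1 a sparse pale one; the
    remaining classes take base/disk colours from an evenly spaced colour
    wheel with rng-jittered disk density, so any two specs differ in base
    colour, disk colour or density by construction.
    """
    if n_classes < 2:
        raise ValueError(f"need at least 2 classes, got {n_classes}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x7E7]))
    specs = [
        TextureClassSpec(0, (0.95, 0.95, 0.93), 1.0, (1.0, 2.0),
                         (0.85, 0.85, 0.85), 0.04),
        TextureClassSpec(1, (0.90, 0.82, 0.86), 4.0, (2.0, 3.5),
                         (0.75, 0.68, 0.72), 0.04),
    ]
    for k in range(2, n_classes):
        hue = (k - 2) / max(n_classes - 2, 1)
        base = colorsys.hsv_to_rgb(hue, 0.45, 0.55)
        blob = colorsys.hsv_to_rgb((hue + 0.35) % 1.0, 0.85, 0.9)
        density = float(rng.uniform(8.0, 22.0))
        specs.append(TextureClassSpec(k, tuple(base), density, (1.0, 3.0),
                                      tuple(blob), 0.05))
    return specs


def render_image(spec: TextureClassSpec, resolution: int,
                 rng: np.random.Generator) -> np.ndarray:
    """Render one (H, W, 3) image in [-1, 1] for ``spec``.

    Pipeline: flat canvas at ``base_color`` → a Poisson(``blob_density``)
    number of disks of ``blob_color`` at uniform positions with uniform
    radius → additive Gaussian noise → clip to [-1, 1].
    """
    if not _is_power_of_two(resolution):
        raise ValueError(f"resolution must be a power of two, got {resolution}")
    if spec.blob_radius_range[1] >= resolution / 2:
        raise ValueError("blob radius too large for this resolution")
    base = np.asarray(spec.base_color, dtype=np.float32) * 2.0 - 1.0
    img = np.broadcast_to(base, (resolution, resolution, 3)).copy()
    n_blobs = rng.poisson(spec.blob_density)
    if n_blobs:
        blob = np.asarray(spec.blob_color, dtype=np.float32) * 2.0 - 1.0
        yy, xx = np.mgrid[0:resolution, 0:resolution]
        for _ in range(n_blobs):
            cy, cx = rng.uniform(0, resolution, size=2)
            r = rng.uniform(*spec.blob_radius_range)
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r
            img[mask] = blob
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd,
                               size=img.shape).astype(np.float32)
    return np.clip(img, -1.0, 1.0).astype(np.float32)


def generate_dataset(config: SyntheticDatasetConfig) -> LabeledImageSet:
    """Render a balanced labelled dataset, bitwise deterministic in the seed."""
    specs = make_class_specs(config.n_classes, config.seed)
    images, labels = [], []
    for spec in specs:
        # per-class child stream: class k's images do not depend on n_classes
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, 1, spec.class_id]))
        for _ in range(config.per_class_count):
            images.append(render_image(spec, config.resolution, rng))
            labels.append(spec.class_id)
    class_names = [f"class{k}" for k in range(config.n_classes)]
    return LabeledImageSet(np.stack(images), np.array(labels), class_names)
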