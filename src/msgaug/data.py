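"""Labeled image batches and directory-of-PNGs I/O.

:class:`LabeledImageSet` is the currency every stage of the pipeline trades
in: an ``(N, H, W, 3)`` float array with pixel values in ``[-1, 1]`` (the
tanh range that generative models emit), integer class labels and class
names.  Conversion to and from 8-bit PNG happens only at the I/O boundary.
The directory layout is one subdirectory per class, one image file per
sample — the same layout used by public tissue-patch collections such as
NCT-CRC-HE-100K, so a user can point the reader at real data.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = ["LabeledImageSet", "save_image_dir", "load_image_dir"]

_IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclasses.dataclass
class LabeledImageSet:
    """A batch of RGB images in [-1, 1] with integer class labels."""

    images: np.ndarray      # (N, H, W, 3) float32 in [-1, 1]
    labels: np.ndarray      # (N,) integers in [0, K)
    class_names: list[str]  # length K

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.class_names = list(self.class_names)
        if self.images.ndim != 4 or self.images.shape[-1] != 3:
            raise ValueError(f"images must be (N, H, W, 3), got {self.images.shape}")
        if self.images.shape[1] != self.images.shape[2]:
            raise ValueError("images must be square")
        if len(self.labels) != len(self.images):
            raise ValueError("labels and images disagree in length")
        k = len(self.class_names)
        if len(self.labels) and (self.labels.min() < 0 or self.labels.max() >= k):
            raise ValueError("labels out of range for class_names")

    # -- convenience --------------------------------------------------------
    def __len__(self) -> int:
        return len(self.images)

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    @property
    def resolution(self) -> int:
        return int(self.images.shape[1])

    def subset(self, index) -> "LabeledImageSet":
        return LabeledImageSet(self.images[index], self.labels[index],
                               self.class_names)

    def restrict_to_class(self, class_id: int) -> "LabeledImageSet":
        return self.subset(self.labels == class_id)

    @staticmethod
    def concatenate(sets: list["LabeledImageSet"]) -> "LabeledImageSet":
        names = sets[0].class_names
        for s in sets[1:]:
            if s.class_names != names:
                raise ValueError("cannot concatenate sets with different classes")
        return LabeledImageSet(
            np.concatenate([s.images for s in sets]),
            np.concatenate([s.labels for s in sets]),
            names,
        )


def _to_uint8(images: np.ndarray) -> np.ndarray:
    return np.clip(np.rint((images + 1.0) * 127.5), 0, 255).astype(np.uint8)


def _from_uint8(images: np.ndarray) -> np.ndarray:
    return images.astype(np.float32) / 127.5 - 1.0


def save_image_dir(dataset: LabeledImageSet, root: str | Path) -> None:
    """Write ``root/<class_name>/<index>.png`` (8-bit RGB)."""
    root = Path(root)
    pixels = _to_uint8(dataset.images)
    counters = {name: 0 for name in dataset.class_names}
    for img, label in zip(pixels, dataset.labels):
        name = dataset.class_names[label]
        cls_dir = root / name
        cls_dir.mkdir(parents=True, exist_ok=True)
        iio.imwrite(cls_dir / f"{counters[name]:05d}.png", img)
        counters[name] += 1


def load_image_dir(root: str | Path) -> LabeledImageSet:
    """Read a directory-of-images layout back into a LabeledImageSet.

    Class subdirectories are sorted by name; ``.png`` and ``.tif`` files are
    accepted, so the reader also loads real stained-tissue collections that
    use this layout.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise FileNotFoundError(f"no class subdirectories under {root}")
    images, labels = [], []
    class_names = [d.name for d in class_dirs]
    for k, d in enumerate(class_dirs):
        files = sorted(f for f in d.iterdir() if f.suffix.lower() in _IMAGE_SUFFIXES)
        for f in files:
            arr = iio.imread(f)
            if arr.ndim == 2:
                arr = np.stack([arr] * 3, axis=-1)
            images.append(_from_uint8(arr[..., :3]))
            labels.append(k)
    return LabeledImageSet(np.stack(images), np.array(labels), class_names)
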