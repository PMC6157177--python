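"""Image preprocessing: mean-RGB centering, crop-and-resize augmentation,
and patch bookkeeping for test-time prediction averaging.

The network consumes fixed-size ``target_size x target_size`` RGB patches.
Fixed-resolution datasets are randomly cropped to a 420x420 window and resized
down; variable-resolution datasets use a window of two-thirds of each image's
height and width.  Cropping m times per source image both standardizes the
input size and augments the sample count; every patch remembers its source
image so softmax outputs can be averaged per image at test time.

Coordinate convention: row-major, origin top-left, crops are half-open
``[r, r+h) x [c, c+w)``.  Resizing is bilinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from .datasets import LabeledImageSet

__all__ = [
    "CropPolicy",
    "FixedCrop",
    "FractionalCrop",
    "AugmentationConfig",
    "PatchSet",
    "subtract_mean_rgb",
    "apply_mean_rgb",
    "crop_and_resize",
    "augment",
    "group_by_source",
]


class CropPolicy:
    """Base class: maps an image's (height, width) to a crop window size."""

    def window(self, height: int, width: int) -> tuple[int, int]:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class FixedCrop(CropPolicy):
    """Fixed square crop window (default 420 px), for fixed-resolution sets."""

    size: int = 420

    def window(self, height: int, width: int) -> tuple[int, int]:
        for name, dim in (("height", height), ("width", width)):
            if dim < self.size:
                raise ValueError(
                    f"image {name} {dim} is smaller than the fixed crop window {self.size}"
                )
        return self.size, self.size


@dataclass(frozen=True)
class FractionalCrop(CropPolicy):
    """Crop window of ``fraction`` of each dimension (default 2/3), for
    variable-resolution sets."""

    fraction: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction <= 1.0:
            raise ValueError(f"fraction must be in (0, 1], got {self.fraction}")

    def window(self, height: int, width: int) -> tuple[int, int]:
        for name, dim in (("height", height), ("width", width)):
            if dim < 2:
                raise ValueError(f"image {name} {dim} too small for fractional crop")
        return int(np.floor(self.fraction * height)), int(np.floor(self.fraction * width))


@dataclass(frozen=True)
class AugmentationConfig:
    """How many patches to cut per source image and how.

    ``m`` is the augmentation multiplier: every source image contributes
    exactly ``m`` independently cropped patches.  Flips, when allowed, are
    applied to each patch with probability 1/2 each.
    """

    m: int = 1
    crop_policy: CropPolicy = field(default_factory=FixedCrop)
    target_size: int = 140
    allow_hflip: bool = True
    allow_vflip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if self.target_size < 1:
            raise ValueError(f"target_size must be >= 1, got {self.target_size}")


@dataclass
class PatchSet:
    """Stack of same-shaped patches with per-patch source id and label."""

    patches: np.ndarray  # (n, t, t, 3) float32
    source_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.patches) == len(self.source_ids) == len(self.labels)):
            raise ValueError("patches, source_ids and labels must have equal lengths")

    def __len__(self) -> int:
        return len(self.patches)


def subtract_mean_rgb(ds: LabeledImageSet) -> tuple[LabeledImageSet, np.ndarray]:
    """Center a (training) image set by its per-channel scalar mean.

    The mean is a 3-vector computed over all pixels of all images in ``ds``
    (scalar per channel, so it applies to variable-resolution images too) and
    is returned so the identical shift can be applied to held-out images via
    :func:`apply_mean_rgb`.
    """
    if len(ds) == 0:
        raise ValueError("cannot compute mean RGB of an empty image set")
    sums = np.zeros(3, dtype=np.float64)
    n_pixels = 0
    for img in ds.images:
        sums += img.reshape(-1, 3).sum(axis=0, dtype=np.float64)
        n_pixels += img.shape[0] * img.shape[1]
    mean_rgb = sums / n_pixels
    return apply_mean_rgb(ds, mean_rgb), mean_rgb


def apply_mean_rgb(ds: LabeledImageSet, mean_rgb: np.ndarray) -> LabeledImageSet:
    """Subtract a previously computed per-channel mean from every image."""
    mean_rgb = np.asarray(mean_rgb, dtype=np.float32)
    centered = [img.astype(np.float32) - mean_rgb for img in ds.images]
    return LabeledImageSet(images=centered, labels=ds.labels.copy(),
                           image_ids=list(ds.image_ids))


def crop_and_resize(
    image: np.ndarray,
    policy: CropPolicy,
    target_size: int = 140,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Cut one uniformly random crop window and bilinearly resize it.

    ``rng`` may be a Generator, an int seed, or None (fresh entropy).  The
    output is always ``target_size x target_size x 3`` float32.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    h, w = image.shape[:2]
    wh, ww = policy.window(h, w)
    r0 = int(rng.integers(0, h - wh + 1))
    c0 = int(rng.integers(0, w - ww + 1))
    window = image[r0 : r0 + wh, c0 : c0 + ww]
    if window.shape[0] == target_size and window.shape[1] == target_size:
        out = window.astype(np.float64)
    else:
        out = _sk_resize(
            window.astype(np.float64),
            (target_size, target_size),
            order=1,
            mode="edge",
            anti_aliasing=False,
            preserve_range=True,
        )
    return out.astype(np.float32)


def augment(ds: LabeledImageSet, cfg: AugmentationConfig) -> PatchSet:
    """Cut exactly ``cfg.m`` patches per source image, with optional flips.

    Each patch is an independent crop; horizontal / vertical flips are then
    applied with probability 1/2 each when allowed.  Deterministic for a
    fixed ``(ds, cfg)`` including ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    patches = np.empty((len(ds) * cfg.m, cfg.target_size, cfg.target_size, 3),
                       dtype=np.float32)
    source_ids: list[str] = []
    labels = np.empty(len(ds) * cfg.m, dtype=int)
    k = 0
    for img, label, image_id in zip(ds.images, ds.labels, ds.image_ids):
        for _ in range(cfg.m):
            patch = crop_and_resize(img, cfg.crop_policy, cfg.target_size, rng)
            if cfg.allow_hflip and rng.random() < 0.5:
                patch = patch[:, ::-1]
            if cfg.allow_vflip and rng.random() < 0.5:
                patch = patch[::-1, :]
            patches[k] = patch
            source_ids.append(image_id)
            labels[k] = label
            k += 1
    return PatchSet(patches=patches, source_ids=source_ids, labels=labels)


def group_by_source(ps: PatchSet) -> dict[str, list[int]]:
    """Partition patch indices by source image id.

    The union of the index lists covers every patch exactly once; each list
    is sorted, so the grouping is invariant to patch order.
    """
    groups: dict[str, list[int]] = {}
    for i, sid in enumerate(ps.source_ids):
        groups.setdefault(sid, []).append(i)
    return {sid: sorted(ix) for sid, ix in sorted(groups.items())}
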