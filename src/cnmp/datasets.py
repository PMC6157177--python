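"""Synthetic labeled image sets with controllable texture/color class structure.

The classifiers in this package assume that image classes differ partly in
oriented texture (periodic intensity patterns) and partly in per-channel color
distribution — the structure found in stained tissue sections and dermoscopy
photographs.  This module renders seeded synthetic datasets with exactly that
structure so the whole pipeline (feature extraction, network training, fusion,
evaluation) can be exercised end to end without any download.

Two fixture families ship as ready-made specs:

* :func:`his_like_spec` — 4 classes, 2828 fixed-resolution 720x480 images with
  the class counts 1026/484/804/514 of a public histology benchmark.
* :func:`isic_like_spec` — 2 imbalanced classes (374/1626) with per-image
  variable resolution, emulating a dermoscopy benchmark.

Both are far too coarse to look like tissue or skin; they only reproduce the
statistical knobs the method is sensitive to (class counts, resolution policy,
texture/color separability).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "ClassRecipe",
    "SyntheticSpec",
    "LabeledImageSet",
    "render_class_image",
    "generate_dataset",
    "split_dataset",
    "save_image_set",
    "load_image_set",
    "his_like_spec",
    "isic_like_spec",
    "complementarity_spec",
    "tiny_spec",
]

TEXTURE_KINDS = ("grating", "checkerboard", "blob-noise")

#: mean of |Z| for standard normal Z; used to center the skewed color noise
_HALF_NORMAL_MEAN = float(np.sqrt(2.0 / np.pi))


@dataclass(frozen=True)
class ClassRecipe:
    """Rendering recipe for one image class.

    Parameters
    ----------
    label
        Integer class label, >= 1.
    texture_kind
        One of ``grating`` (sinusoidal bands), ``checkerboard`` (alternating
        square cells) or ``blob-noise`` (low-pass filtered noise).
    orientation
        Texture orientation in degrees (gratings only; 0 means bands vary
        along image columns).
    period
        Spatial period of the texture in pixels (cell edge for checkerboards,
        smoothing scale for blob noise).  Must be >= 2.
    amplitude
        Peak texture modulation in intensity units added to every channel.
    color_mean
        Per-channel (R, G, B) mean intensity in [0, 255].
    color_spread
        Per-channel standard deviation of the per-pixel color noise (>= 0).
    color_skew
        Per-channel skew direction in {-1, 0, +1}: sign of the third central
        moment of the color noise (half-normal based), 0 for symmetric.
    count
        Number of images to generate for this class (>= 0).
    """

    label: int
    texture_kind: str = "grating"
    orientation: float = 0.0
    period: float = 8.0
    amplitude: float = 40.0
    color_mean: tuple[float, float, float] = (127.0, 127.0, 127.0)
    color_spread: tuple[float, float, float] = (0.0, 0.0, 0.0)
    color_skew: tuple[int, int, int] = (0, 0, 0)
    count: int = 0

    def validate(self) -> None:
        if self.label < 1:
            raise ValueError(f"label must be >= 1, got {self.label}")
        if self.texture_kind not in TEXTURE_KINDS:
            raise ValueError(
                f"unknown texture_kind {self.texture_kind!r}; expected one of {TEXTURE_KINDS}"
            )
        if self.period < 2:
            raise ValueError(f"period must be >= 2 pixels, got {self.period}")
        if self.count < 0:
            raise ValueError(f"count must be >= 0, got {self.count}")
        for mu in self.color_mean:
            if not 0.0 <= mu <= 255.0:
                raise ValueError(f"color_mean entries must lie in [0, 255], got {mu}")
        for sd in self.color_spread:
            if sd < 0:
                raise ValueError(f"color_spread entries must be >= 0, got {sd}")
        for sk in self.color_skew:
            if sk not in (-1, 0, 1):
                raise ValueError(f"color_skew entries must be in {{-1,0,1}}, got {sk}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full dataset specification: class recipes + global rendering knobs.

    ``image_size`` is either a single ``(height, width)`` pair (fixed
    resolution) or a sequence of pairs from which each image's resolution is
    drawn uniformly (variable resolution).
    """

    recipes: tuple[ClassRecipe, ...]
    image_size: tuple[int, int] | tuple[tuple[int, int], ...] = (64, 64)
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if len(self.recipes) == 0:
            raise ValueError("SyntheticSpec needs at least one recipe")
        labels = [r.label for r in self.recipes]
        if len(set(labels)) != len(labels):
            raise ValueError(f"recipe labels must be distinct, got {labels}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for r in self.recipes:
            r.validate()

    @property
    def size_choices(self) -> tuple[tuple[int, int], ...]:
        sz = self.image_size
        if len(sz) == 2 and isinstance(sz[0], (int, np.integer)):
            return (tuple(int(v) for v in sz),)  # type: ignore[return-value]
        return tuple(tuple(int(v) for v in pair) for pair in sz)  # type: ignore[union-attr]


@dataclass
class LabeledImageSet:
    """Images + integer labels + unique per-image source ids.

    ``images`` is a list (not a stacked array) because resolutions may vary
    per image.  Pixel values are uint8 in [0, 255] as generated; downstream
    preprocessing converts to centered float arrays.
    """

    images: list[np.ndarray]
    labels: np.ndarray
    image_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not self.image_ids:
            self.image_ids = [f"img_{i:05d}" for i in range(len(self.images))]
        if not (len(self.images) == len(self.labels) == len(self.image_ids)):
            raise ValueError("images, labels and image_ids must have equal lengths")
        if len(set(self.image_ids)) != len(self.image_ids):
            raise ValueError("image_ids must be unique")

    def __len__(self) -> int:
        return len(self.images)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def subset(self, indices: Sequence[int]) -> "LabeledImageSet":
        idx = list(indices)
        return LabeledImageSet(
            images=[self.images[i] for i in idx],
            labels=self.labels[idx],
            image_ids=[self.image_ids[i] for i in idx],
        )


def _texture_field(recipe: ClassRecipe, height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-amplitude texture pattern in [-1, 1] for one image."""
    rows, cols = np.mgrid[0:height, 0:width].astype(np.float64)
    if recipe.texture_kind == "grating":
        theta = np.deg2rad(recipe.orientation)
        phase = 2.0 * np.pi * (cols * np.cos(theta) + rows * np.sin(theta)) / recipe.period
        return np.sin(phase)
    if recipe.texture_kind == "checkerboard":
        cell = max(int(round(recipe.period)), 1)
        parity = (rows.astype(int) // cell + cols.astype(int) // cell) % 2
        return 2.0 * parity - 1.0
    if recipe.texture_kind == "blob-noise":
        raw = rng.standard_normal((height, width))
        smooth = gaussian_filter(raw, sigma=recipe.period / 2.0)
        peak = np.max(np.abs(smooth))
        return smooth / peak if peak > 0 else smooth
    raise ValueError(f"unknown texture_kind {recipe.texture_kind!r}")


def _skewed_noise(shape: tuple[int, ...], skew: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-scale noise with sign(skewness) == ``skew`` (half-normal based)."""
    z = rng.standard_normal(shape)
    if skew == 0:
        return z
    return float(skew) * (np.abs(z) - _HALF_NORMAL_MEAN)


def render_class_image(
    recipe: ClassRecipe, height: int, width: int, seed: int | np.random.SeedSequence
) -> np.ndarray:
    """Render one ``height x width x 3`` uint8 image from a class recipe.

    Deterministic per ``(recipe, height, width, seed)``.  The image is the
    class texture scaled by ``amplitude``, shifted by the per-channel color
    mean, plus per-pixel color noise with the recipe's spread and skew,
    clipped to [0, 255].
    """
    recipe.validate()
    if min(height, width) < recipe.period:
        raise ValueError(
            f"image size {height}x{width} smaller than texture period {recipe.period}"
        )
    rng = np.random.default_rng(seed)
    tex = _texture_field(recipe, height, width, rng)
    img = np.empty((height, width, 3), dtype=np.float64)
    for c in range(3):
        chan = recipe.color_mean[c] + recipe.amplitude * tex
        if recipe.color_spread[c] > 0:
            chan = chan + recipe.color_spread[c] * _skewed_noise(
                (height, width), recipe.color_skew[c], rng
            )
        img[:, :, c] = chan
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Generate the full dataset a spec describes.

    Per-image randomness is drawn from ``SeedSequence([spec.seed, label, i])``
    so regeneration under an identical spec+seed is bit-identical and
    independent of generation order.  Additive i.i.d. Gaussian pixel noise
    with ``spec.noise_sd`` is applied after rendering, then clipped.
    """
    spec.validate()
    sizes = spec.size_choices
    images: list[np.ndarray] = []
    labels: list[int] = []
    ids: list[str] = []
    for recipe in spec.recipes:
        for i in range(recipe.count):
            ss = np.random.SeedSequence([int(spec.seed), int(recipe.label), i])
            rng = np.random.default_rng(ss)
            if len(sizes) == 1:
                h, w = sizes[0]
            else:
                h, w = sizes[rng.integers(len(sizes))]
            img = render_class_image(recipe, h, w, ss.spawn(1)[0])
            if spec.noise_sd > 0:
                noisy = img.astype(np.float64) + rng.normal(0.0, spec.noise_sd, img.shape)
                img = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)
            images.append(img)
            labels.append(recipe.label)
            ids.append(f"c{recipe.label}_{i:05d}")
    return LabeledImageSet(images=images, labels=np.asarray(labels, dtype=int), image_ids=ids)


def _allocate(n: int, ratios: np.ndarray) -> np.ndarray:
    """Largest-remainder allocation of ``n`` items across normalized ratios."""
    target = n * ratios
    base = np.floor(target).astype(int)
    short = n - int(base.sum())
    # distribute the remainder to the largest fractional parts; ties go to
    # the earlier split (train before val before test)
    order = np.argsort(-(target - base), kind="stable")
    base[order[:short]] += 1
    return base


def split_dataset(
    ds: LabeledImageSet,
    ratios: tuple[float, float, float],
    seed: int,
) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Stratified train/validation/test split of source images.

    Ratios are normalized to sum to 1; within every class the images are
    shuffled with a seeded generator and allocated to the three splits by
    largest-remainder rounding, so the splits partition the id set exactly
    and every class appears in every split with a positive ratio.  A class
    too small to place at least one image in each positive-ratio split
    raises instead of being silently dropped.
    """
    r = np.asarray(ratios, dtype=float)
    if len(r) != 3 or np.any(r < 0) or r.sum() <= 0:
        raise ValueError(f"ratios must be three nonnegative numbers with a positive sum, got {ratios}")
    r = r / r.sum()
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    for label in np.unique(ds.labels):
        idx = np.flatnonzero(ds.labels == label)
        counts = _allocate(len(idx), r)
        if np.any((counts == 0) & (r > 0)):
            raise ValueError(
                f"class {label} has only {len(idx)} images; cannot place at least one "
                f"in every split with positive ratio {tuple(r)}"
            )
        rng.shuffle(idx)
        stops = np.cumsum(counts)
        parts[0].extend(idx[: stops[0]])
        parts[1].extend(idx[stops[0] : stops[1]])
        parts[2].extend(idx[stops[1] : stops[2]])
    return tuple(ds.subset(sorted(p)) for p in parts)  # type: ignore[return-value]


def save_image_set(ds: LabeledImageSet, directory: str | Path) -> Path:
    """Write PNGs into per-class subdirectories plus a CSV manifest.

    Returns the manifest path.  Layout: ``<dir>/class_<label>/<image_id>.png``
    and ``<dir>/manifest.csv`` with columns image_id, path, label.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "path", "label"])
        for img, label, image_id in zip(ds.images, ds.labels, ds.image_ids):
            sub = directory / f"class_{label}"
            sub.mkdir(exist_ok=True)
            rel = f"class_{label}/{image_id}.png"
            Image.fromarray(img).save(directory / rel)
            writer.writerow([image_id, rel, int(label)])
    return manifest


def load_image_set(directory: str | Path) -> LabeledImageSet:
    """Load a dataset previously written by :func:`save_image_set`."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    if not manifest.exists():
        raise FileNotFoundError(f"no manifest.csv under {directory}")
    images, labels, ids = [], [], []
    with open(manifest, newline="") as fh:
        for row in csv.DictReader(fh):
            images.append(np.asarray(Image.open(directory / row["path"]).convert("RGB")))
            labels.append(int(row["label"]))
            ids.append(row["image_id"])
    return LabeledImageSet(images=images, labels=np.asarray(labels), image_ids=ids)


# ---------------------------------------------------------------------------
# ready-made fixture specs
# ---------------------------------------------------------------------------

def _four_class_recipes(counts: tuple[int, int, int, int]) -> tuple[ClassRecipe, ...]:
    """Four classes where texture kind separates {1,2} from {3,4} and color
    separates odd labels from even labels — and, by construction, neither
    feature family can do the other family's job:

    * the texture contrast is a kind difference (grating vs checkerboard)
      with amplitudes matched in variance (sine has variance a^2/2, the
      +-a checkerboard a^2), so the per-channel color moments (mean, spread,
      skew) are the same across texture groups;
    * the two color means are luminance-matched (0.299 R + 0.587 G + 0.114 B
      equal), so the gray image — and with it every GLCM statistic — is the
      same across color groups.

    A kind/variance contrast is also required because the 8-dim texture
    feature is invariant to 90-degree rotation by construction; an
    orientation-only contrast would be invisible to it.
    """
    red = (150.0, 110.0, 80.0)    # luminance 118.5
    blue = (104.0, 110.0, 200.0)  # luminance 118.5
    spread = (12.0, 12.0, 12.0)
    grating_amp = 55.0
    checker_amp = grating_amp / np.sqrt(2.0)  # equal texture variance
    return (
        ClassRecipe(1, "grating", orientation=30.0, period=8, amplitude=grating_amp,
                    color_mean=red, color_spread=spread, count=counts[0]),
        ClassRecipe(2, "grating", orientation=30.0, period=8, amplitude=grating_amp,
                    color_mean=blue, color_spread=spread, count=counts[1]),
        ClassRecipe(3, "checkerboard", period=6, amplitude=checker_amp,
                    color_mean=red, color_spread=spread, count=counts[2]),
        ClassRecipe(4, "checkerboard", period=6, amplitude=checker_amp,
                    color_mean=blue, color_spread=spread, count=counts[3]),
    )


def his_like_spec(seed: int = 0) -> SyntheticSpec:
    """Histology-benchmark-like fixture: 4 classes, counts 1026/484/804/514,
    fixed 720x480 resolution (height 480, width 720)."""
    return SyntheticSpec(
        recipes=_four_class_recipes((1026, 484, 804, 514)),
        image_size=(480, 720),
        noise_sd=8.0,
        seed=seed,
    )


def isic_like_spec(seed: int = 0) -> SyntheticSpec:
    """Dermoscopy-benchmark-like fixture: 2 imbalanced classes (374 vs 1626),
    per-image resolution drawn from a small set of photograph-like sizes."""
    recipes = (
        ClassRecipe(1, "blob-noise", period=10, amplitude=60.0,
                    color_mean=(120.0, 70.0, 60.0), color_spread=(18.0, 12.0, 12.0),
                    color_skew=(1, 0, 0), count=374),
        ClassRecipe(2, "grating", orientation=0.0, period=16, amplitude=25.0,
                    color_mean=(190.0, 140.0, 120.0), color_spread=(10.0, 10.0, 10.0),
                    count=1626),
    )
    return SyntheticSpec(
        recipes=recipes,
        image_size=((450, 600), (480, 640), (576, 768)),
        noise_sd=8.0,
        seed=seed,
    )


def complementarity_spec(n_per_class: int = 32, size: tuple[int, int] = (96, 96),
                         noise_sd: float = 10.0, seed: int = 0) -> SyntheticSpec:
    """The four-class texture/color complementarity fixture at study size.

    Texture features alone can only separate {1,2} from {3,4}; color moments
    alone only odd from even labels; their concatenation separates all four.
    """
    return SyntheticSpec(
        recipes=_four_class_recipes((n_per_class,) * 4),
        image_size=size,
        noise_sd=noise_sd,
        seed=seed,
    )


def tiny_spec(n_per_class: int = 15, size: tuple[int, int] = (64, 64), seed: int = 0,
              noise_sd: float = 0.0) -> SyntheticSpec:
    """Tiny noiseless 4-class profile (default 60 images, 64x64) for unit tests."""
    return SyntheticSpec(
        recipes=_four_class_recipes((n_per_class,) * 4),
        image_size=size,
        noise_sd=noise_sd,
        seed=seed,
    )
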