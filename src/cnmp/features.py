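"""Traditional (handcrafted) image features: GLCM texture statistics and
color moments, concatenated into the 17-dimensional low-level vector LF.

Texture: the gray-level co-occurrence matrix G is the normalized joint
distribution of quantized gray levels at pixel pairs one step apart, computed
at the four angles 0/45/90/135 degrees.  From each G we take

* ASM  (angular second moment)  = sum G(i,j)^2
* ENT  (entropy)                = -sum G(i,j) ln G(i,j),  0 ln 0 := 0
* CON  (contrast)               = sum (i-j)^2 G(i,j)
* COR  (correlation)            = (sum ij G(i,j) - mu_x mu_y) / (sigma_x sigma_y)

and summarize each statistic by its mean and standard deviation over the four
angles, giving an 8-vector that is invariant to 90-degree image rotation.

Color: per channel c the mean A_c, the (population) standard deviation V_c
and the signed cube root of the third central moment S_c, giving 9 values.

Conventions pinned here because the literature varies: G is accumulated
symmetrically (both (a,b) and (b,a)) and normalized to a probability matrix
before any statistic; gray levels are indexed 0..s-1; entropy uses the
natural log; a degenerate COR (zero marginal deviation, e.g. a constant
patch) is reported as 0 with a flag rather than NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import PatchSet, group_by_source

__all__ = [
    "GLCM",
    "TextureStats",
    "Standardizer",
    "GLCM_OFFSETS",
    "to_gray_quantized",
    "compute_glcm",
    "glcm_stats",
    "texture_vector",
    "color_moments",
    "extract_traditional",
    "extract_for_patchset",
    "fit_standardizer",
    "FEATURE_NAMES",
]

#: pixel displacements (dr, dc) for angles 0, 45, 90, 135 degrees at distance 1
GLCM_OFFSETS: tuple[tuple[int, int], ...] = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

FEATURE_NAMES: tuple[str, ...] = (
    "asm_mean", "asm_std", "ent_mean", "ent_std",
    "con_mean", "con_std", "cor_mean", "cor_std",
    "r_mean", "r_std", "r_skew",
    "g_mean", "g_std", "g_skew",
    "b_mean", "b_std", "b_skew",
)


@dataclass
class GLCM:
    """Normalized symmetric co-occurrence probability matrix for one offset."""

    G: np.ndarray
    s: int
    offset: tuple[int, int]

    @property
    def marginal_x(self) -> np.ndarray:
        return self.G.sum(axis=1)

    @property
    def mu_x(self) -> float:
        return float(np.arange(self.s) @ self.marginal_x)

    @property
    def mu_y(self) -> float:
        # symmetric matrix: both marginals coincide
        return float(np.arange(self.s) @ self.G.sum(axis=0))

    @property
    def sigma_x(self) -> float:
        i = np.arange(self.s)
        return float(np.sqrt(((i - self.mu_x) ** 2) @ self.marginal_x))

    @property
    def sigma_y(self) -> float:
        j = np.arange(self.s)
        return float(np.sqrt(((j - self.mu_y) ** 2) @ self.G.sum(axis=0)))


@dataclass(frozen=True)
class TextureStats:
    """The four scalar GLCM statistics for one offset."""

    asm: float
    ent: float
    con: float
    cor: float
    cor_degenerate: bool = False

    def as_array(self) -> np.ndarray:
        return np.array([self.asm, self.ent, self.con, self.cor])


def to_gray_quantized(image: np.ndarray, s: int = 16) -> np.ndarray:
    """Luminance conversion then uniform quantization into ``s`` gray levels.

    gray = 0.299 R + 0.587 G + 0.114 B; [0, 255] is divided into s equal
    bins, so the output values lie in {0, ..., s-1}.
    """
    if s < 2:
        raise ValueError(f"need at least 2 gray levels, got s={s}")
    image = np.asarray(image, dtype=np.float64)
    gray = 0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
    q = np.floor(gray * s / 256.0).astype(np.int64)
    return np.clip(q, 0, s - 1)


def compute_glcm(gray: np.ndarray, offset: tuple[int, int], s: int | None = None) -> GLCM:
    """Accumulate the symmetric co-occurrence matrix for one pixel offset.

    Every in-bounds ordered pair (p, p + offset) contributes to both
    G(a, b) and G(b, a); the matrix is then normalized to sum to 1.
    """
    if offset not in GLCM_OFFSETS:
        raise ValueError(f"offset must be one of {GLCM_OFFSETS}, got {offset}")
    gray = np.asarray(gray)
    if s is None:
        s = int(gray.max()) + 1
    dr, dc = offset
    h, w = gray.shape
    # source block and its displaced partner, via half-open slicing
    r0, r1 = max(0, -dr), min(h, h - dr)
    c0, c1 = max(0, -dc), min(w, w - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError(f"image of shape {gray.shape} has no pixel pairs for offset {offset}")
    a = gray[r0:r1, c0:c1].ravel()
    b = gray[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    G = np.zeros((s, s), dtype=np.float64)
    np.add.at(G, (a, b), 1.0)
    np.add.at(G, (b, a), 1.0)
    return GLCM(G=G / G.sum(), s=s, offset=offset)


def glcm_stats(g: GLCM) -> TextureStats:
    """Evaluate ASM, ENT, CON and COR on a normalized GLCM."""
    G = g.G
    if not np.isclose(G.sum(), 1.0, atol=1e-8):
        raise ValueError("GLCM must be normalized to sum to 1")
    asm = float(np.sum(G * G))
    nz = G[G > 0]
    ent = float(-np.sum(nz * np.log(nz)))
    i, j = np.indices(G.shape)
    con = float(np.sum((i - j) ** 2 * G))
    sx, sy = g.sigma_x, g.sigma_y
    if sx * sy == 0.0:
        return TextureStats(asm=asm, ent=ent, con=con, cor=0.0, cor_degenerate=True)
    cor = float((np.sum(i * j * G) - g.mu_x * g.mu_y) / (sx * sy))
    return TextureStats(asm=asm, ent=ent, con=con, cor=cor)


def texture_vector(image: np.ndarray, s: int = 16) -> np.ndarray:
    """8 texture features: mean and std over the four angles of each statistic.

    Order: (ASM_mean, ASM_std, ENT_mean, ENT_std, CON_mean, CON_std,
    COR_mean, COR_std).  Std is the population standard deviation.
    """
    gray = to_gray_quantized(image, s)
    stats = np.stack([glcm_stats(compute_glcm(gray, off, s)).as_array()
                      for off in GLCM_OFFSETS])
    out = np.empty(8)
    out[0::2] = stats.mean(axis=0)
    out[1::2] = stats.std(axis=0)
    return out


def color_moments(image: np.ndarray) -> np.ndarray:
    """9 color features: per channel (mean, std, signed-cube-root skew moment).

    Order R(A,V,S), G(A,V,S), B(A,V,S).  V is the population standard
    deviation; S = sign(mu3) |mu3|^(1/3) keeps the third-moment summary real
    for negatively skewed channels and on the intensity scale.
    """
    image = np.asarray(image, dtype=np.float64)
    flat = image.reshape(-1, 3)
    a = flat.mean(axis=0)
    dev = flat - a
    v = np.sqrt(np.mean(dev ** 2, axis=0))
    mu3 = np.mean(dev ** 3, axis=0)
    sk = np.sign(mu3) * np.abs(mu3) ** (1.0 / 3.0)
    return np.column_stack([a, v, sk]).ravel()


def extract_traditional(image: np.ndarray, s: int = 16) -> np.ndarray:
    """The 17-dim traditional feature vector LF = texture(8) + color(9)."""
    return np.concatenate([texture_vector(image, s), color_moments(image)])


def extract_for_patchset(ps: PatchSet, s: int = 16) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Per-source-image traditional features, averaged over each image's patches.

    Intended for patch sets cut from *raw* (uncentered) images, since color
    moments and the gray quantizer are defined on the [0, 255] scale.  If a
    mean-centered patch set is passed anyway, patches are shifted back onto
    the intensity scale before feature extraction (see :func:`_to_intensity`).

    Returns (source_ids, features (n_images, 17), labels).
    """
    groups = group_by_source(ps)
    ids = list(groups.keys())
    feats = np.empty((len(ids), 17))
    labels = np.empty(len(ids), dtype=int)
    for k, sid in enumerate(ids):
        idx = groups[sid]
        per_patch = [extract_traditional(_to_intensity(ps.patches[i]), s) for i in idx]
        feats[k] = np.mean(per_patch, axis=0)
        labels[k] = ps.labels[idx[0]]
    return ids, feats, labels


def _to_intensity(patch: np.ndarray) -> np.ndarray:
    """Map a mean-centered float patch back onto the [0, 255] intensity scale."""
    arr = np.asarray(patch, dtype=np.float64)
    if arr.min() >= 0.0 and arr.max() <= 255.0:
        return arr
    return np.clip(arr + 128.0, 0.0, 255.0)


@dataclass
class Standardizer:
    """Per-feature location/scale transform learned on training data.

    Features with zero spread get scale 1 so they map to exactly 0 instead
    of dividing by zero.
    """

    location: np.ndarray
    scale: np.ndarray

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=np.float64) - self.location) / self.scale


def fit_standardizer(vectors: np.ndarray) -> Standardizer:
    """Fit mean/std standardization on a (n_samples, n_features) matrix."""
    vectors = np.asarray(vectors, dtype=np.float64)
    if vectors.ndim != 2 or vectors.shape[0] == 0:
        raise ValueError("need a non-empty 2-D feature matrix")
    loc = vectors.mean(axis=0)
    scale = vectors.std(axis=0)
    # a feature that is constant up to rounding gets scale 1 (maps to ~0)
    tiny = 1e-12 * np.maximum(1.0, np.abs(loc))
    scale = np.where(scale > tiny, scale, 1.0)
    return Standardizer(location=loc, scale=scale)
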