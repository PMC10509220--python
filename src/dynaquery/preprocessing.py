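"""Image preprocessing pipeline and metadata normalization.

The pipeline P(·) maps a raw scan slice to a model-ready array:
crop the approximate heart region → resize to 160×200 with bilinear
interpolation → collapse to one channel → min–max normalize to [−1, 1].
Acquisition metadata is squashed elementwise into (0, 1) by the standard
logistic function S(x) = eˣ / (eˣ + 1).

Stochastic augmentation (small affine transforms plus brightness/contrast
jitter) is applied to training samples and to candidates at query-scoring
time, never to the validation holdout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from skimage.transform import resize as _skimage_resize

from .data_pools import Sample

TARGET_HEIGHT = 160
TARGET_WIDTH = 200

# crop window, in sixteenths of the raw image: columns [2/16, 10/16),
# rows [5/16, 12/16) — the empirically located heart region
CROP_COL_LO, CROP_COL_HI = 2, 10
CROP_ROW_LO, CROP_ROW_HI = 5, 12


@dataclass(frozen=True)
class AugmentationParams:
    """Bounds of the stochastic augmentation draws (all inclusive, symmetric
    where signed).  Zero everywhere gives the identity transform."""

    max_rotation_deg: float = 5.0
    max_scale_frac: float = 0.05
    max_shear_px: float = 5.0
    max_brightness_frac: float = 0.10
    max_contrast_frac: float = 0.10

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class MetadataVector:
    """Raw acquisition metadata and its logistic-normalized counterpart.

    The default composition (M = 22) is: patient position (x, y, z), proper
    Euler angles (φ, θ, ψ), two 3-component image-orientation vectors, the
    relative slice-position scalar, and the scout scan's position (3) and
    orientation (6).
    """

    raw: np.ndarray
    normalized: np.ndarray

    def __post_init__(self) -> None:
        if self.raw.shape != self.normalized.shape:
            raise ValueError("raw and normalized metadata must have equal length")


def crop_heart_region(image: np.ndarray) -> np.ndarray:
    """Crop rows [5H/16, 12H/16) and columns [2W/16, 10W/16), floor-exact."""
    image = np.asarray(image)
    h, w = image.shape[:2]
    if h < 16 or w < 16:
        raise ValueError(f"image must be at least 16x16 to crop, got {h}x{w}")
    r0, r1 = (CROP_ROW_LO * h) // 16, (CROP_ROW_HI * h) // 16
    c0, c1 = (CROP_COL_LO * w) // 16, (CROP_COL_HI * w) // 16
    return image[r0:r1, c0:c1]


def resize_bilinear(image: np.ndarray) -> np.ndarray:
    """Resize to 160×200 with bilinear interpolation (align-corners-false
    pixel-area convention; constant images stay constant)."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot resize an empty image")
    return _skimage_resize(
        image,
        (TARGET_HEIGHT, TARGET_WIDTH) + image.shape[2:],
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse a multi-channel image to one channel by channel averaging;
    single-channel input passes through."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 3:
        return image.mean(axis=2)
    return image


def to_unit_range(image: np.ndarray) -> np.ndarray:
    """Min–max map onto [−1, 1]; a constant image maps to all zeros."""
    image = np.asarray(image, dtype=float)
    lo, hi = float(image.min()), float(image.max())
    if hi == lo:
        return np.zeros_like(image)
    return 2.0 * (image - lo) / (hi - lo) - 1.0


def logistic_normalize(raw: np.ndarray) -> np.ndarray:
    """Elementwise standard logistic S(x) = eˣ/(eˣ+1), mapping ℝ → (0, 1).

    (Floating point saturates to exactly 0/1 beyond |x| ≈ 37; inputs are
    expected at acquisition-metadata scale.)
    """
    raw = np.asarray(raw, dtype=float)
    if not np.all(np.isfinite(raw)):
        raise ValueError("metadata entries must be finite")
    return expit(raw)


_GRID_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _pixel_grid(h: int, w: int) -> np.ndarray:
    """Cached (2, h·w) array of centered (row, col) pixel coordinates."""
    key = (h, w)
    if key not in _GRID_CACHE:
        rows, cols = np.mgrid[0:h, 0:w].astype(np.float32)
        grid = np.stack([rows.ravel(), cols.ravel()])
        grid[0] -= (h - 1) / 2.0
        grid[1] -= (w - 1) / 2.0
        _GRID_CACHE[key] = grid
    return _GRID_CACHE[key]


def augment_batch(
    images: np.ndarray,
    params: AugmentationParams = AugmentationParams(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One independent stochastic augmentation draw per image in a batch.

    Affine part (per image): rotation uniform in ±max_rotation_deg,
    isotropic scale uniform in 1 ± max_scale_frac, horizontal shear
    displacing the top edge by up to max_shear_px pixels relative to the
    bottom; composed into a single bilinear warp about the image center,
    with out-of-field pixels filled with the image minimum.  Photometric
    part: brightness and contrast factors uniform within the ±10% bounds
    (multiplicative jitter semantics).  Values are re-clamped to [−1, 1];
    shape is preserved.  The whole batch is warped in one vectorized gather.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    images = np.asarray(images)
    n, h, w = images.shape

    angles = np.deg2rad(rng.uniform(-params.max_rotation_deg, params.max_rotation_deg, n))
    scales = rng.uniform(1.0 - params.max_scale_frac, 1.0 + params.max_scale_frac, n)
    shears = rng.uniform(0.0, params.max_shear_px, n) / max(h - 1, 1)
    cos, sin = np.cos(angles), np.sin(angles)
    # forward maps (n, 2, 2): rotation ∘ shear, then isotropic scale
    forward = np.empty((n, 2, 2))
    forward[:, 0, 0] = cos - sin * shears
    forward[:, 0, 1] = -sin
    forward[:, 1, 0] = sin + cos * shears
    forward[:, 1, 1] = cos
    forward *= scales[:, None, None]
    inverse = np.linalg.inv(forward).astype(np.float32)

    grid = _pixel_grid(h, w)  # centered output coordinates, shared
    coords = np.einsum("nij,jp->nip", inverse, grid)
    coords[:, 0] += (h - 1) / 2.0
    coords[:, 1] += (w - 1) / 2.0

    inside = (
        (coords[:, 0] >= 0)
        & (coords[:, 0] <= h - 1)
        & (coords[:, 1] >= 0)
        & (coords[:, 1] <= w - 1)
    )
    r0 = np.clip(np.floor(coords[:, 0]).astype(np.int32), 0, h - 2)
    c0 = np.clip(np.floor(coords[:, 1]).astype(np.int32), 0, w - 2)
    fr = coords[:, 0] - r0
    fc = coords[:, 1] - c0
    flat = images.reshape(n, h * w)
    idx = r0 * w + c0
    rows = np.arange(n)[:, None]
    i00 = flat[rows, idx]
    i01 = flat[rows, idx + 1]
    i10 = flat[rows, idx + w]
    i11 = flat[rows, idx + w + 1]
    out = i00 * (1 - fr) * (1 - fc) + i01 * (1 - fr) * fc + i10 * fr * (1 - fc) + i11 * fr * fc
    fill = images.min(axis=(1, 2))
    out = np.where(inside, out, fill[:, None])

    brightness = rng.uniform(
        1.0 - params.max_brightness_frac, 1.0 + params.max_brightness_frac, n
    )[:, None]
    contrast = rng.uniform(1.0 - params.max_contrast_frac, 1.0 + params.max_contrast_frac, n)[
        :, None
    ]
    out = out * brightness
    mean = out.mean(axis=1, keepdims=True)
    out = (out - mean) * contrast + mean
    return np.clip(out, -1.0, 1.0).reshape(n, h, w).astype(images.dtype, copy=False)


def augment(
    image: np.ndarray,
    params: AugmentationParams = AugmentationParams(),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """One stochastic augmentation draw on a single prepared image; see
    :func:`augment_batch` for the transform family."""
    image = np.asarray(image)
    return augment_batch(image[None], params, rng)[0]


def preprocess(sample: Sample) -> tuple[np.ndarray, MetadataVector]:
    """Full deterministic pipeline: crop → resize → grayscale → [−1,1] image,
    plus logistic-normalized metadata."""
    img = crop_heart_region(np.asarray(sample.image, dtype=float))
    img = resize_bilinear(img)
    img = to_grayscale(img)
    img = to_unit_range(img)
    raw = np.asarray(sample.metadata_raw, dtype=float)
    meta = MetadataVector(raw=raw, normalized=logistic_normalize(raw))
    return img, meta
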