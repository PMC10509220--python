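"""Synthetic desk-scale data with the statistical structure the method
assumes, plus synthetic loss traces for scheduler tests.

Images emulate the task's visual contrast: the *included* class is a clean,
bright, near-circular vessel cross-section centered in the heart-region crop
window; the *excluded* class perturbs it by one of three mechanisms —
axis-ratio deformation (an obliquely cut vessel looks elongated), center
displacement out of the crop region (wrong slice position), or blur (poor
image quality).  A single ``difficulty`` knob in [0, 1] shrinks the
perturbation magnitude: at 0 the classes are trivially separable, at 1 the
class-conditional distributions are identical.  Metadata is class-conditional
Gaussian with mean separation ``metadata_separation·(1−difficulty)``.
The default class balance is ~2:1 (120 included / 62 excluded), the scaled
shape of a 670/347 training split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import ndimage

from .data_pools import Dataset, Label, Sample
from .preprocessing import CROP_COL_HI, CROP_COL_LO, CROP_ROW_HI, CROP_ROW_LO


@dataclass(frozen=True)
class SyntheticConfig:
    n_included: int = 120
    n_excluded: int = 62
    image_height: int = 64
    image_width: int = 64
    difficulty: float = 0.4
    metadata_dim: int = 22
    metadata_separation: float = 3.0
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_included < 1 or self.n_excluded < 1:
            raise ValueError("class counts must be >= 1")
        if not 0 <= self.difficulty <= 1:
            raise ValueError("difficulty must be in [0, 1]")
        if not 0 <= self.label_noise < 1:
            raise ValueError("label_noise must be in [0, 1)")
        if self.metadata_separation < 0 or self.metadata_dim < 1:
            raise ValueError("metadata_separation >= 0 and metadata_dim >= 1 required")


def _render_ellipse(
    h: int, w: int, center: np.ndarray, a: float, b: float, angle: float, intensity: float
) -> np.ndarray:
    rows, cols = np.mgrid[0:h, 0:w].astype(float)
    dr, dc = rows - center[0], cols - center[1]
    cos, sin = math.cos(angle), math.sin(angle)
    u = dr * cos + dc * sin
    v = -dr * sin + dc * cos
    r2 = (u / a) ** 2 + (v / b) ** 2
    return intensity * np.clip(1.2 - r2, 0.0, 1.0) / 1.2


def generate_image(label: Label | str, config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """One raw grayscale image of the requested class.

    The generator first draws everything an *included* image needs
    (background noise, base radius/axis jitter, center jitter, angle), then —
    for *excluded* — draws a perturbation mode and magnitude scaled by
    (1 − difficulty).  At difficulty 1 the perturbation vanishes, so the two
    class-conditional distributions (and, stream for stream, the pixels)
    coincide.
    """
    label = Label.coerce(label)
    h, w = config.image_height, config.image_width
    img = rng.normal(0.1, 0.05, size=(h, w))
    crop_center = np.array(
        [(CROP_ROW_LO + CROP_ROW_HI) / 32.0 * h, (CROP_COL_LO + CROP_COL_HI) / 32.0 * w]
    )
    radius = 0.09 * min(h, w)
    ratio = 1.0 + rng.uniform(-0.08, 0.08)
    center = crop_center + rng.normal(0.0, 1.0, size=2)
    angle = rng.uniform(0.0, math.pi)
    blur_sigma = 0.5

    if label is Label.EXCLUDED:
        m = 1.0 - config.difficulty
        mode = rng.integers(0, 3)
        direction = rng.uniform(0.0, 2 * math.pi)
        stretch = rng.uniform(0.8, 1.2)
        if mode == 0:  # oblique cut: elongated cross-section
            ratio *= 1.0 + 1.5 * m * stretch
        elif mode == 1:  # mispositioned slice: structure drifts out of the crop
            shift = 0.30 * min(h, w) * m * stretch
            center = center + shift * np.array([math.sin(direction), math.cos(direction)])
        else:  # poor quality: strong blur
            blur_sigma += 3.0 * m * stretch

    a = radius * math.sqrt(ratio)
    b = radius / math.sqrt(ratio)
    img += _render_ellipse(h, w, center, a, b, angle, intensity=1.0)
    return ndimage.gaussian_filter(img, blur_sigma)


def generate_metadata(
    label: Label | str, config: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """Class-conditional Gaussian metadata: unit variances, mean difference of
    norm ``metadata_separation · (1 − difficulty)`` along a fixed direction."""
    label = Label.coerce(label)
    m = config.metadata_dim
    direction = np.ones(m) / math.sqrt(m)
    delta = config.metadata_separation * (1.0 - config.difficulty)
    sign = 0.5 if label is Label.INCLUDED else -0.5
    return sign * delta * direction + rng.standard_normal(m)


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """A full synthetic dataset: unique ids, concealed labels (with an
    optional ``label_noise`` fraction flipped), reproducible under the seed."""
    rng = np.random.default_rng(config.seed)
    samples, labels = [], {}
    spec = [(Label.INCLUDED, config.n_included), (Label.EXCLUDED, config.n_excluded)]
    i = 0
    for label, count in spec:
        for _ in range(count):
            sid = f"s{i:05d}"
            image = generate_image(label, config, rng)
            meta = generate_metadata(label, config, rng)
            recorded = label
            if config.label_noise > 0 and rng.random() < config.label_noise:
                recorded = Label.EXCLUDED if label is Label.INCLUDED else Label.INCLUDED
            samples.append(Sample(sample_id=sid, image=image, metadata_raw=meta))
            labels[sid] = recorded
            i += 1
    return Dataset(samples, labels)


@dataclass(frozen=True)
class LossTraceSpec:
    """Synthetic per-epoch training-loss trace for scheduler unit tests."""

    pattern: Literal["exponential_decay", "plateau_after", "noisy_constant", "piecewise"]
    length: int
    noise_sd: float = 0.0
    seed: int = 0
    init_loss: float = 1.0
    decay: float = 0.8
    plateau_epoch: int = 10
    constant_level: float = 0.5
    segment_levels: tuple[float, ...] = (1.0, 0.25, 0.5)

    def __post_init__(self) -> None:
        if self.length < 1 or self.noise_sd < 0:
            raise ValueError("length >= 1 and noise_sd >= 0 required")


def generate_loss_trace(spec: LossTraceSpec) -> list[float]:
    """Generate a non-negative loss sequence of the requested shape.

    ``exponential_decay``: l₀·rᵗ;  ``plateau_after``: decay for
    ``plateau_epoch`` epochs then constant at the reached level;
    ``noisy_constant``: a flat level;  ``piecewise``: equal-length constant
    segments at ``segment_levels``.  Gaussian noise (sd ``noise_sd``) is
    added and the result clamped at 0.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(1, spec.length + 1, dtype=float)
    if spec.pattern == "exponential_decay":
        base = spec.init_loss * spec.decay**t
    elif spec.pattern == "plateau_after":
        base = spec.init_loss * spec.decay ** np.minimum(t, spec.plateau_epoch)
    elif spec.pattern == "noisy_constant":
        base = np.full(spec.length, spec.constant_level)
    elif spec.pattern == "piecewise":
        seg = math.ceil(spec.length / len(spec.segment_levels))
        base = np.array(
            [spec.segment_levels[min(int(i // seg), len(spec.segment_levels) - 1)]
             for i in range(spec.length)]
        )
    else:  # pragma: no cover - guarded by Literal
        raise ValueError(f"unknown pattern {spec.pattern!r}")
    if spec.noise_sd > 0:
        base = base + rng.normal(0.0, spec.noise_sd, size=spec.length)
    return [float(x) for x in np.clip(base, 0.0, None)]
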