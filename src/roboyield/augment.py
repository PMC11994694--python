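"""Camera-sensor-effect augmentation.

Counting models trained on one camera under one set of field conditions
over-count when tested on imagery from other cameras or lighting; augmenting
the training set with randomized sensor effects — additive noise, Gaussian
blur, chromatic aberration, exposure gain — narrows that gap. Each original
image receives exactly one augmented variant, with per-image effect
intensities drawn independently from configured ranges.

Effects compose in a fixed order: blur, chromatic aberration, exposure,
noise — noise last, matching where it arises in a physical sensor chain.
Point annotations are untouched by all four effects (the chromatic shift
moves only color planes relative to the luminance-reference geometry).

Images are float arrays in [0, 1]; every operator clips back to that domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage


class AugmentError(ValueError):
    pass


def _check_nonneg(name: str, value: float) -> None:
    if value < 0:
        raise AugmentError(f"{name} must be non-negative, got {value}")


def add_noise(image: np.ndarray, sd: float, rng: np.random.Generator | int = 0) -> np.ndarray:
    """Additive Gaussian noise of standard deviation ``sd`` (intensity units)."""
    _check_nonneg("noise sd", sd)
    if sd == 0:
        return image.copy()
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return np.clip(image + rng.normal(0.0, sd, image.shape), 0.0, 1.0).astype(image.dtype)


def blur(image: np.ndarray, sigma: float) -> np.ndarray:
    """Gaussian blur of the spatial axes (normalized kernel)."""
    _check_nonneg("blur sigma", sigma)
    if sigma == 0:
        return image.copy()
    sigmas = (sigma, sigma, 0) if image.ndim == 3 else (sigma, sigma)
    return np.clip(ndimage.gaussian_filter(image, sigmas), 0.0, 1.0).astype(image.dtype)


def chromatic_aberration(image: np.ndarray, shift: float) -> np.ndarray:
    """Color fringing: red and blue planes shifted laterally by ``±shift``
    pixels (sub-pixel, bilinear); green is the geometric reference."""
    _check_nonneg("chromatic shift", shift)
    if shift == 0 or image.ndim != 3:
        return image.copy()
    out = image.copy()
    out[..., 0] = ndimage.shift(image[..., 0], (0, shift), order=1, mode="nearest")
    out[..., 2] = ndimage.shift(image[..., 2], (0, -shift), order=1, mode="nearest")
    return np.clip(out, 0.0, 1.0).astype(image.dtype)


def adjust_exposure(image: np.ndarray, gain: float) -> np.ndarray:
    """Multiplicative exposure gain, clipped to [0, 1]."""
    _check_nonneg("exposure gain", gain)
    return np.clip(image * gain, 0.0, 1.0).astype(image.dtype)


@dataclass(frozen=True)
class AugmentConfig:
    """Ranges from which per-image effect intensities are drawn.

    Each range is (low, high) with low <= high; a degenerate range fixes the
    effect. The defaults produce mild, clearly visible corruption on [0, 1]
    images.
    """

    noise_sd_range: tuple[float, float] = (0.0, 0.06)
    blur_sigma_range: tuple[float, float] = (0.0, 1.5)
    ca_shift_range: tuple[float, float] = (0.0, 1.5)
    exposure_gain_range: tuple[float, float] = (0.7, 1.3)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_sd_range", "blur_sigma_range", "ca_shift_range",
                     "exposure_gain_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise AugmentError(f"{name} has low > high: ({lo}, {hi})")
            if name != "exposure_gain_range" and lo < 0:
                raise AugmentError(f"{name} low bound must be >= 0")


def augment_image(
    image: np.ndarray,
    noise_sd: float,
    blur_sigma: float,
    ca_shift: float,
    exposure_gain: float,
    rng: np.random.Generator | int = 0,
) -> np.ndarray:
    """Apply the four effects in the fixed order blur -> chromatic aberration
    -> exposure -> noise."""
    out = blur(image, blur_sigma)
    out = chromatic_aberration(out, ca_shift)
    out = adjust_exposure(out, exposure_gain)
    return add_noise(out, noise_sd, rng)


def random_augment(
    images: list[np.ndarray], cfg: AugmentConfig
) -> tuple[list[np.ndarray], pd.DataFrame]:
    """One augmented variant per original, with independently drawn per-image
    intensities; fully reproducible from ``cfg.rng_seed``.

    Returns the augmented images and a per-image parameter log.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    out = []
    log_rows = []
    for i, img in enumerate(images):
        params = {
            "noise_sd": rng.uniform(*cfg.noise_sd_range),
            "blur_sigma": rng.uniform(*cfg.blur_sigma_range),
            "ca_shift": rng.uniform(*cfg.ca_shift_range),
            "exposure_gain": rng.uniform(*cfg.exposure_gain_range),
        }
        out.append(augment_image(img, rng=rng, **params))
        log_rows.append({"index": i, **params})
    return out, pd.DataFrame(log_rows)
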