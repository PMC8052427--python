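"""Intensity normalization, isotropic resampling and gray-level discretization."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class PreprocessedVolume:
    """Whole-volume z-scored, isotropically resampled image + mask."""

    image: np.ndarray
    mask: np.ndarray
    target_spacing_mm: float
    normalization_mean: float
    normalization_sd: float


@dataclass
class DiscretizedVolume:
    """Integer gray levels 1..Ng over the mask (0 outside)."""

    levels: np.ndarray
    mask: np.ndarray
    bin_width: float
    n_levels: int


def preprocess(
    volume: np.ndarray,
    mask: np.ndarray,
    spacing_mm,
    target_spacing_mm: float = 1.0,
) -> PreprocessedVolume:
    """Z-score the whole volume, then resample to isotropic spacing.

    Normalization statistics are taken over the full volumetric stack
    (not the mask alone). Intensities are resampled trilinearly, the
    mask by nearest neighbor, both with ``scipy.ndimage.zoom``. If the
    grid is already isotropic at the target spacing the data pass
    through unchanged.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    mean = float(volume.mean())
    sd = float(volume.std())
    if sd < 1e-12:
        raise ValueError("constant volume: z-score normalization undefined")
    z = (volume - mean) / sd

    spacing = np.asarray(spacing_mm, dtype=float)
    if np.allclose(spacing, target_spacing_mm):
        return PreprocessedVolume(z, mask, target_spacing_mm, mean, sd)
    factors = spacing / float(target_spacing_mm)
    img_r = ndimage.zoom(z, factors, order=1, mode="nearest", prefilter=False)
    mask_r = ndimage.zoom(
        mask.astype(np.uint8), factors, order=0, mode="nearest", prefilter=False
    ).astype(bool)
    if not mask_r.any():
        raise ValueError("mask vanished during resampling (region below target spacing)")
    return PreprocessedVolume(img_r, mask_r, target_spacing_mm, mean, sd)


def discretize(pv: PreprocessedVolume, bin_width: float = 0.25) -> DiscretizedVolume:
    """Fixed-bin-width discretization of in-mask intensities.

    Level(x) = floor((x - min_in_mask) / bin_width) + 1, giving integer
    levels 1..Ng anchored at the in-mask minimum.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    mask = pv.mask
    if not mask.any():
        raise ValueError("empty mask")
    vals = pv.image[mask]
    lo = vals.min()
    levels = np.zeros(pv.image.shape, dtype=np.int32)
    levels[mask] = np.floor((pv.image[mask] - lo) / bin_width).astype(np.int32) + 1
    return DiscretizedVolume(levels, mask, bin_width, int(levels[mask].max()))
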