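"""Cell masking and marker-channel enhancement.

The whole-cell stain is bright and contiguous, so the cell mask is a
blur + Otsu segmentation with hole filling and small-region removal.
The marker channel goes through the enhancement chain applied before
binarisation: rolling-ball-style background subtraction, Gaussian
smoothing, percentile contrast stretch, and median despeckling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

__all__ = ["CellMask", "EnhanceConfig", "make_cell_mask", "enhance_marker", "binarize"]


@dataclass(frozen=True)
class CellMask:
    """Boolean cell-occupancy mask plus its foreground coverage."""

    mask: np.ndarray
    coverage_fraction: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))
        cov = float(self.mask.mean()) if self.mask.size else 0.0
        object.__setattr__(self, "coverage_fraction", cov)

    @classmethod
    def from_array(cls, mask: np.ndarray) -> "CellMask":
        mask = np.asarray(mask, dtype=bool)
        return cls(mask=mask, coverage_fraction=float(mask.mean()))


@dataclass(frozen=True)
class EnhanceConfig:
    """Parameters of the marker enhancement chain.

    Defaults are standard values for 1024x1024 widefield puncta/tubule
    imagery at ~0.1 um/px; all are exposed in the run configuration.
    """

    background_radius_px: int = 50
    smooth_sigma_px: float = 1.0
    contrast_saturation_fraction: float = 0.003
    despeckle_radius_px: int = 1
    threshold_method: str = "otsu"  # {"otsu", "fixed"}
    fixed_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.background_radius_px <= 0:
            raise ValueError("background_radius_px must be > 0")
        if self.smooth_sigma_px <= 0:
            raise ValueError("smooth_sigma_px must be > 0")
        if not 0 <= self.contrast_saturation_fraction <= 0.05:
            raise ValueError("contrast_saturation_fraction must be in [0, 0.05]")
        if self.despeckle_radius_px <= 0:
            raise ValueError("despeckle_radius_px must be > 0")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold_method requires fixed_threshold")


_STRUCT8 = np.ones((3, 3), dtype=bool)


def remove_small_regions(mask: np.ndarray, min_px: int) -> np.ndarray:
    """Drop 8-connected foreground regions smaller than ``min_px``."""
    if min_px <= 1 or not mask.any():
        return mask
    labels, n = ndimage.label(mask, structure=_STRUCT8)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    return np.isin(labels, keep)


def fill_small_holes(mask: np.ndarray, max_px: int = 4) -> np.ndarray:
    """Fill enclosed background holes of at most ``max_px`` pixels.

    Tiny holes block topology-preserving thinning (they survive as
    rings), cluttering the skeleton.
    """
    if not mask.any():
        return mask
    holes = ndimage.binary_fill_holes(mask) & ~mask
    labels, n = ndimage.label(holes)  # 4-connectivity for background
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    small = np.flatnonzero(sizes <= max_px) + 1
    return mask | np.isin(labels, small)


def _validated(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid, dtype=np.float64)
    if grid.ndim != 2:
        raise ValueError("expected a 2-D intensity grid")
    if not np.isfinite(grid).all():
        raise ValueError("intensities must be finite")
    if (grid < 0).any():
        raise ValueError("intensities must be non-negative")
    return grid


def make_cell_mask(
    cell_channel: np.ndarray,
    blur_sigma_px: float = 5.0,
    min_region_px: int = 500,
) -> CellMask:
    """Segment cell-occupied pixels from the whole-cell stain.

    Gaussian blur, Otsu over the whole frame, hole filling, then removal
    of regions smaller than ``min_region_px``. A featureless (constant)
    frame yields an all-false mask.
    """
    grid = _validated(cell_channel)
    blurred = ndimage.gaussian_filter(grid, sigma=blur_sigma_px)
    if np.ptp(blurred) == 0:
        return CellMask.from_array(np.zeros(grid.shape, dtype=bool))
    thr = threshold_otsu(blurred)
    mask = blurred > thr
    mask = ndimage.binary_fill_holes(mask)
    if min_region_px > 0:
        mask = remove_small_regions(mask, int(min_region_px))
    return CellMask.from_array(mask)


def subtract_background(grid: np.ndarray, radius_px: int) -> np.ndarray:
    """Rolling-ball-style background subtraction.

    The background is estimated by a greyscale opening with a
    (2*radius+1)-pixel box footprint; structures narrower than the
    footprint survive subtraction, broad background does not.
    """
    r = int(radius_px)
    size = 2 * r + 1
    # pad before opening so the dilation step can restore edge levels;
    # otherwise an intensity ramp leaves a residual band ~radius wide
    padded = np.pad(grid, r, mode="edge")
    background = ndimage.grey_opening(padded, size=(size, size))[r:-r, r:-r]
    return grid - background


def enhance_marker(marker_channel: np.ndarray, config: EnhanceConfig | None = None) -> np.ndarray:
    """Apply the enhancement chain to the marker channel.

    Order: background subtraction -> median despeckle -> Gaussian
    smoothing -> percentile contrast stretch (to [0, 1]). Despeckling
    precedes smoothing because a median can only reject an impulse
    while it is still single-pixel; after blurring it is a blob the
    median keeps. Output is non-negative and the same shape as the input.
    """
    config = config or EnhanceConfig()
    grid = _validated(marker_channel)

    out = subtract_background(grid, config.background_radius_px)
    out = np.clip(out, 0.0, None)

    r = int(config.despeckle_radius_px)
    out = ndimage.median_filter(out, footprint=disk(r), mode="nearest")

    out = ndimage.gaussian_filter(out, sigma=config.smooth_sigma_px)

    f = config.contrast_saturation_fraction
    lo, hi = np.percentile(out, [100.0 * f, 100.0 * (1.0 - f)])
    if hi > lo:
        out = np.clip((out - lo) / (hi - lo), 0.0, 1.0)
    else:
        out = np.zeros_like(out)
    return out


def binarize(
    enhanced: np.ndarray,
    mask: CellMask | np.ndarray,
    config: EnhanceConfig | None = None,
) -> np.ndarray:
    """Threshold the enhanced marker inside the cell mask.

    The threshold (Otsu or fixed) is computed over masked pixels only;
    the foreground is always a subset of the mask. An empty mask or a
    zero-variance masked region yields an empty foreground.
    """
    config = config or EnhanceConfig()
    grid = np.asarray(enhanced, dtype=np.float64)
    m = mask.mask if isinstance(mask, CellMask) else np.asarray(mask, dtype=bool)
    if grid.shape != m.shape:
        raise ValueError("enhanced image and mask shapes differ")
    if not m.any():
        return np.zeros_like(m)
    values = grid[m]
    if config.threshold_method == "fixed":
        thr = float(config.fixed_threshold)
    else:
        if np.ptp(values) == 0:  # featureless region: nothing to segment
            return np.zeros_like(m)
        thr = threshold_otsu(values)
    return (grid > thr) & m
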