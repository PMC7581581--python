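"""Percent-darkness quantification of segment photographs.

Deterministic re-implementation of the manual ImageJ recipe used to measure
how much of the 2nd abdominal segment is covered by dark pigment:

1. convert the photograph to 8-bit greyscale,
2. smooth with a median filter of 2-pixel radius,
3. threshold the dark (chromatophore) pixels within the hand-drawn segment
   ROI — automated here with Otsu's method restricted to ROI pixels,
4. report the dark fraction of the ROI as a percentage.

The human threshold adjustment of the original recipe is replaced by Otsu's
criterion so that runs are reproducible and blind; a fixed threshold can be
supplied instead.  Pixel coordinates are 0-based, row-major, origin at the
top-left corner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import disk

logger = logging.getLogger(__name__)

#: ITU-R 601 luminance weights for R, G, B.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

#: Minimum ROI intensity spread (grey levels) for thresholding to engage.
#: Below this the ROI is treated as chromatophore-free: Otsu would otherwise
#: happily bisect pure background noise and report a large spurious cover.
DEFAULT_MIN_CONTRAST = 50


@dataclass(frozen=True)
class CoverResult:
    """Percent of ROI pixels classified as dark pigment."""

    percent_dark: float
    threshold_used: float
    n_dark_pixels: int
    n_roi_pixels: int


def to_greyscale_8bit(image: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel 8-bit image to single-channel greyscale.

    RGB input is combined with the ITU-R 601 luminance weights
    0.299 R + 0.587 G + 0.114 B, rounded to nearest integer and clipped to
    [0, 255].  Single-channel input passes through unchanged (as uint8).
    """
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(np.uint8)
    if image.ndim == 3 and image.shape[2] == 3:
        luma = image[..., 0] * LUMA_WEIGHTS[0] + image[..., 1] * LUMA_WEIGHTS[1] + image[..., 2] * LUMA_WEIGHTS[2]
        return np.clip(np.rint(luma), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported channel layout: shape {image.shape} (expected HxW or HxWx3)")


def median_smooth(grey: np.ndarray, radius: int = 2) -> np.ndarray:
    """Median-filter a greyscale image over a disk neighbourhood.

    Each pixel is replaced by the median of the pixels within Euclidean
    distance ``radius`` (a disk footprint, matching the radius semantics of
    ImageJ's rank filters); image borders are handled by reflection.
    """
    grey = np.asarray(grey)
    if grey.ndim != 2:
        raise ValueError("median_smooth expects a single-channel image")
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    footprint = disk(radius)
    return ndimage.median_filter(grey, footprint=footprint, mode="reflect").astype(np.uint8)


def threshold_dark(
    grey: np.ndarray,
    roi_mask: np.ndarray,
    threshold: float | None = None,
    min_contrast: int = DEFAULT_MIN_CONTRAST,
) -> tuple[np.ndarray, float]:
    """Classify dark pigment pixels inside the ROI.

    Otsu's threshold is computed over ROI pixels only; pixels strictly below
    it (and inside the ROI) are marked dark.  If the ROI intensity spread is
    below ``min_contrast`` grey levels the image is considered free of
    pigment and an empty mask is returned with threshold 0 — a necessary
    guard because Otsu always produces *a* split, even of pure noise.  A
    supplied fixed ``threshold`` bypasses both Otsu and the guard.

    Returns
    -------
    (binary mask, threshold used)

    Raises
    ------
    ValueError
        Empty ROI, or constant ROI intensity (degenerate histogram).
    """
    grey = np.asarray(grey)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if grey.shape != roi_mask.shape:
        raise ValueError(f"image shape {grey.shape} != mask shape {roi_mask.shape}")
    roi_values = grey[roi_mask]
    if roi_values.size == 0:
        raise ValueError("empty ROI; nothing to threshold")
    if threshold is None:
        lo, hi = int(roi_values.min()), int(roi_values.max())
        if lo == hi:
            raise ValueError("degenerate histogram; no threshold (constant ROI intensity)")
        if hi - lo < min_contrast:
            logger.info(
                "ROI intensity spread %d < %d grey levels; treating as pigment-free",
                hi - lo,
                min_contrast,
            )
            return np.zeros_like(roi_mask, dtype=bool), 0.0
        # skimage returns the upper value of the lower class; the class
        # boundary sits between integer grey levels, so record it at the
        # half-integer and mark strictly-below pixels dark
        threshold = float(threshold_otsu(roi_values)) + 0.5
    binary = (grey < threshold) & roi_mask
    return binary, float(threshold)


def percent_cover(binary: np.ndarray, roi_mask: np.ndarray, threshold_used: float = float("nan")) -> CoverResult:
    """Percent of ROI pixels marked dark, on the 0-100 scale."""
    binary = np.asarray(binary).astype(bool)
    roi_mask = np.asarray(roi_mask).astype(bool)
    if binary.shape != roi_mask.shape:
        raise ValueError(f"binary shape {binary.shape} != mask shape {roi_mask.shape}")
    n_roi = int(roi_mask.sum())
    if n_roi == 0:
        raise ValueError("empty ROI; percent cover undefined")
    n_dark = int((binary & roi_mask).sum())
    return CoverResult(
        percent_dark=100.0 * n_dark / n_roi,
        threshold_used=threshold_used,
        n_dark_pixels=n_dark,
        n_roi_pixels=n_roi,
    )


def quantify_image(
    image: np.ndarray,
    roi_mask: np.ndarray,
    median_radius: int = 2,
    threshold: float | None = None,
    min_contrast: int = DEFAULT_MIN_CONTRAST,
) -> CoverResult:
    """Full percent-darkness recipe: greyscale -> median -> threshold -> cover.

    ``threshold`` fixes the dark/background cut instead of Otsu's automatic
    choice; ``median_radius`` is the smoothing disk radius in pixels.
    """
    try:
        grey = to_greyscale_8bit(image)
    except ValueError as exc:
        raise ValueError(f"greyscale stage: {exc}") from exc
    try:
        smooth = median_smooth(grey, radius=median_radius)
    except ValueError as exc:
        raise ValueError(f"median stage: {exc}") from exc
    try:
        binary, used = threshold_dark(smooth, roi_mask, threshold=threshold, min_contrast=min_contrast)
        return percent_cover(binary, roi_mask, threshold_used=used)
    except ValueError as exc:
        raise ValueError(f"threshold stage: {exc}") from exc
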