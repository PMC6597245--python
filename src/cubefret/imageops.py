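"""Deterministic image-processing primitives.

Background subtraction (rolling ball as a grayscale morphological opening
with a ball-shaped structuring element), Gaussian smoothing, unsharp masking
(display only), validity masking in the PixFRET convention (signal above
``threshold`` background-noise standard deviations in every channel, below
detector saturation), bright-organelle masking, and ROI reduction.

All primitives are pure functions: identical inputs give identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure

from .errors import EstimationError, ParameterError

log = logging.getLogger(__name__)


@dataclass
class ProcessingParams:
    """Numeric knobs of the map-processing chain.

    Defaults follow the standard seFRET workflow: rolling-ball radius 50 px,
    PixFRET threshold 1 (in units of background noise sd) and Gaussian blur
    sigma 2 px; unsharp mask sigma 3 / weight 0.7 for display images only.
    """

    rolling_ball_radius_px: int = 50
    gaussian_sigma_px: float = 2.0
    threshold: float = 1.0
    unsharp_sigma_px: float = 3.0
    unsharp_weight: float = 0.7
    saturation_margin: float = 1.0

    def __post_init__(self):
        if self.rolling_ball_radius_px < 1:
            raise ParameterError("rolling_ball_radius_px must be >= 1")
        if self.gaussian_sigma_px < 0:
            raise ParameterError("gaussian_sigma_px must be >= 0")
        if self.threshold < 0:
            raise ParameterError("threshold must be >= 0")
        if not (0 <= self.unsharp_weight < 1):
            raise ParameterError("unsharp_weight must be in [0, 1)")
        if not (0 < self.saturation_margin <= 1):
            raise ParameterError("saturation_margin must be in (0, 1]")


def _ball_element(radius: int, paraboloid: bool = False):
    """Footprint (disk) and height profile of the rolling element."""
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    rho2 = yy ** 2 + xx ** 2
    footprint = rho2 <= r * r
    if paraboloid:
        heights = np.where(footprint, r - rho2 / (2.0 * max(r, 1)), 0.0)
    else:
        heights = np.where(footprint, np.sqrt(np.maximum(r * r - rho2, 0.0)), 0.0)
    return footprint, heights


def rolling_ball_subtract(image: np.ndarray, radius_px: int,
                          paraboloid: bool = False):
    """Rolling-ball background subtraction.

    The background is the grayscale morphological opening of the image with a
    ball-shaped (hemisphere-height) structuring element of the given radius;
    ``corrected = clip(image - background, 0)``.  ``paraboloid=True`` swaps
    the element for a paraboloid of the same radius.

    Returns ``(background, corrected)``.
    """
    image = np.asarray(image, dtype=float)
    if radius_px < 1:
        raise ParameterError("radius must be >= 1")
    if radius_px > max(image.shape):
        raise ParameterError("rolling-ball radius exceeds both image dimensions")
    if not np.all(np.isfinite(image)):
        raise ParameterError("image must be finite")
    footprint, heights = _ball_element(radius_px, paraboloid)
    eroded = ndi.grey_erosion(image, footprint=footprint, structure=heights,
                              mode="nearest")
    background = ndi.grey_dilation(eroded, footprint=footprint, structure=heights,
                                   mode="nearest")
    corrected = np.clip(image - background, 0.0, None)
    return background, corrected


def gaussian_blur(image: np.ndarray, sigma_px: float) -> np.ndarray:
    """Gaussian smoothing; ``sigma_px = 0`` is the identity."""
    image = np.asarray(image, dtype=float)
    if sigma_px < 0:
        raise ParameterError("sigma must be >= 0")
    if sigma_px == 0:
        return image.copy()
    return ndi.gaussian_filter(image, sigma=sigma_px, mode="nearest")


def unsharp_mask(image: np.ndarray, sigma_px: float, weight: float) -> np.ndarray:
    """Contrast enhancement for display figures only — never quantification.

    ``result = (image - weight * blur(image, sigma)) / (1 - weight)``.
    """
    if not (0 <= weight < 1):
        raise ParameterError("unsharp weight must be in [0, 1)")
    image = np.asarray(image, dtype=float)
    log.info("unsharp_mask applied (display only; excluded from quantification)")
    return (image - weight * gaussian_blur(image, sigma_px)) / (1.0 - weight)


def estimate_background_sd(image: np.ndarray,
                           background_mask: np.ndarray | None = None,
                           rolling_ball_radius_px: int = 50) -> float:
    """Robust background-noise sd of one channel.

    With a ``background_mask`` (e.g. the synthetic generator's label-0
    pixels) the sd is the scaled median absolute deviation of the masked
    pixels.  Without one, the MAD of the rolling-ball residual
    (image - opening) over its below-median pixels is used, which isolates
    background texture from cellular signal in real images.
    """
    image = np.asarray(image, dtype=float)
    if background_mask is not None:
        sample = image[np.asarray(background_mask, dtype=bool)]
    else:
        _, corrected = rolling_ball_subtract(image, rolling_ball_radius_px)
        sample = corrected[corrected <= np.median(corrected)]
    if sample.size == 0:
        raise EstimationError("empty background sample")
    return float(1.4826 * np.median(np.abs(sample - np.median(sample))))


def validity_mask(processed_channels, raw_channels, params: ProcessingParams,
                  saturation_level: float, background_sds) -> np.ndarray:
    """Pixel validity for quantification.

    A pixel is valid iff, in every channel, the processed (background
    subtracted, blurred) intensity exceeds ``threshold`` times that channel's
    background-noise sd, and the raw intensity is below
    ``saturation_margin * saturation_level``.
    """
    processed_channels = [np.asarray(c, dtype=float) for c in processed_channels]
    shape = processed_channels[0].shape
    if any(c.shape != shape for c in processed_channels):
        raise ParameterError("channels must share one shape")
    mask = np.ones(shape, dtype=bool)
    ceiling = params.saturation_margin * saturation_level
    for proc, raw, sd in zip(processed_channels, raw_channels, background_sds):
        mask &= proc > params.threshold * sd
        mask &= np.asarray(raw, dtype=float) < ceiling
    return mask


def golgi_mask(image: np.ndarray, percentile: float = 98.0,
               min_area_px: int = 20) -> np.ndarray:
    """Mask the high-intensity juxta-nuclear (Golgi-like) regions.

    Connected components of pixels above the given intensity percentile,
    discarding components smaller than ``min_area_px``.
    """
    image = np.asarray(image, dtype=float)
    if not (50 < percentile <= 100):
        raise ParameterError("percentile must be in (50, 100]")
    if np.ptp(image) == 0:
        raise ParameterError("image has no dynamic range; threshold degenerate")
    thresh = np.percentile(image, percentile)
    above = image > thresh
    labels = measure.label(above, connectivity=2)
    mask = np.zeros_like(above)
    for region in measure.regionprops(labels):
        if region.area >= min_area_px:
            mask[labels == region.label] = True
    return mask


def roi_reduce(data: np.ndarray, roi_mask: np.ndarray,
               validity: np.ndarray | None = None,
               reducer: str = "mean"):
    """Reduce a map (H,W) or stack (T,H,W) over a ROI's valid pixels.

    Returns ``(values, n_valid)``; a time point with zero valid ROI pixels
    yields NaN with a logged warning.
    """
    if reducer not in ("mean", "median"):
        raise ParameterError(f"unknown reducer {reducer!r}")
    data = np.asarray(data, dtype=float)
    single = data.ndim == 2
    frames = data[None] if single else data
    roi_mask = np.asarray(roi_mask, dtype=bool)
    func = np.nanmean if reducer == "mean" else np.nanmedian
    values, n_valid = [], []
    for t, frame in enumerate(frames):
        m = roi_mask.copy()
        if validity is not None:
            v = validity[None] if validity.ndim == 2 else validity
            m &= v[min(t, len(v) - 1)]
        sel = frame[m]
        sel = sel[np.isfinite(sel)]
        n_valid.append(sel.size)
        if sel.size == 0:
            log.warning("roi_reduce: zero valid pixels at time index %d", t)
            values.append(np.nan)
        else:
            values.append(float(func(sel)))
    values = np.asarray(values)
    n_valid = np.asarray(n_valid)
    if single:
        return float(values[0]), int(n_valid[0])
    return values, n_valid
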