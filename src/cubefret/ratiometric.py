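"""Ratiometric two-channel sensor analysis (FRET / Cerulean ratio).

For ratiometric biosensors (e.g. an ionic-strength sensor) the readout is
the per-pixel ratio of the FRET channel to the donor (Cerulean) channel on
background-subtracted images, reduced over whole-cell ROIs, normalized to
the baseline condition (1 = baseline), with spatial line profiles and a
coefficient-of-variation statistic for within-cell uniformity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (EstimationError, NormalizationError, ParameterError,
                     ValidationError)
from .imageops import roi_reduce
from .io_core import ConditionProtocol, RoiSet

log = logging.getLogger(__name__)


@dataclass
class RatioTimeCourse:
    """Per-cell sensor-ratio trace, normalized so 1 = baseline."""

    cell_id: str
    t_s: np.ndarray
    ratio_raw: np.ndarray
    condition: list
    ratio_norm: np.ndarray | None = None
    baseline_mean: float | None = None


def ratio_map(i_fret: np.ndarray, i_cerulean: np.ndarray,
              background_level: float = 0.0, floor: float = 1.0):
    """Per-pixel FRET/Cerulean ratio with a validity mask.

    Both channels are background-subtracted by a constant offset; the ratio
    is defined only where the denominator exceeds ``floor`` (typically 3x the
    background noise sd), preventing ratio blow-up.  Invalid pixels are NaN.

    Returns ``(ratio, valid)``.
    """
    i_fret = np.asarray(i_fret, dtype=float)
    i_cerulean = np.asarray(i_cerulean, dtype=float)
    if i_fret.shape != i_cerulean.shape:
        raise ValidationError("channel shapes must match")
    if floor <= 0:
        raise ParameterError("floor must be positive")
    num = i_fret - background_level
    den = i_cerulean - background_level
    valid = den > floor
    out = np.full(i_fret.shape, np.nan)
    out[valid] = num[valid] / den[valid]
    return out, valid


def ratio_timecourse(i_fret_stack, i_cerulean_stack, timestamps, rois: RoiSet,
                     protocol: ConditionProtocol,
                     background_level: float = 0.0, floor: float = 1.0,
                     baseline_condition: str = "iso") -> list:
    """Per-cell normalized ratio traces from a two-channel movie.

    The baseline is the initial run of baseline-condition time points (>= 3
    required); normalized ratio is ``ratio_raw / baseline_mean`` so the
    baseline sits at 1.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    labels = protocol.labels_for(timestamps)
    maps = [ratio_map(i_fret_stack[t], i_cerulean_stack[t],
                      background_level, floor)
            for t in range(len(timestamps))]
    out = []
    for cell in rois.of_kind("cell"):
        vals = []
        for rmap, valid in maps:
            v, _ = roi_reduce(rmap, cell.mask, valid[None], "mean")
            vals.append(v)
        vals = np.asarray(vals)
        tc = RatioTimeCourse(cell_id=cell.roi_id, t_s=timestamps,
                             ratio_raw=vals, condition=list(labels))
        idx = []
        for i, lab in enumerate(labels):
            if lab == baseline_condition:
                idx.append(i)
            else:
                break
        if len(idx) < 3:
            raise NormalizationError("baseline window has < 3 points")
        base = float(np.nanmean(vals[idx]))
        if not np.isfinite(base) or base <= 0:
            raise NormalizationError("baseline ratio mean not positive")
        tc.ratio_norm = vals / base
        tc.baseline_mean = base
        out.append(tc)
    return out


def line_profile(rmap: np.ndarray, line_roi, n_samples: int = 100):
    """Bilinear profile of a map along a two-endpoint line ROI.

    Samples ``n_samples`` evenly spaced points along the segment; NaN map
    pixels yield missing samples.  Returns ``(distance_px, values)``.
    """
    pts = np.asarray(line_roi.endpoints if hasattr(line_roi, "endpoints")
                     else line_roi, dtype=float)
    (x0, y0), (x1, y1) = pts
    if np.hypot(x1 - x0, y1 - y0) == 0:
        raise ParameterError("degenerate line: endpoints coincide")
    t = np.linspace(0.0, 1.0, n_samples)
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    values = map_coordinates(np.asarray(rmap, dtype=float), [ys, xs],
                             order=1, mode="constant", cval=np.nan)
    dist = t * np.hypot(x1 - x0, y1 - y0)
    return dist, values


def spatial_uniformity(change_map: np.ndarray, cell_mask: np.ndarray,
                       min_pixels: int = 50) -> float:
    """Coefficient of variation of a normalized change map within a cell.

    Operationalizes "homogeneous over the cell": sd/mean of the per-pixel
    normalized ratio change over valid cell pixels.  Requires >= 50 valid
    pixels and a positive mean.
    """
    sel = np.asarray(change_map, dtype=float)[np.asarray(cell_mask, dtype=bool)]
    sel = sel[np.isfinite(sel)]
    if sel.size < min_pixels:
        raise EstimationError(f"only {sel.size} valid pixels (< {min_pixels})")
    mean = float(sel.mean())
    if mean <= 0:
        raise EstimationError("mean change must be positive for a CV")
    return float(sel.std() / mean)
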