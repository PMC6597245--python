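"""Corrected sensitized-emission FRET maps and per-cell time courses.

The central readout: pixel-wise corrected FRET

    cFRET = (I_DA - beta * I_DD - gamma * I_AA) / I_AA

computed on background-subtracted, blurred channels with PixFRET-style
validity masking, then reduced over whole-cell ROIs and normalized per cell
to the mean cFRET during the baseline (isotonic) condition, expressed in
percent (100 = baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .calibration import CorrectionFactors
from .errors import NormalizationError, WindowError
from .imageops import (ProcessingParams, estimate_background_sd, gaussian_blur,
                       roi_reduce, rolling_ball_subtract, validity_mask)
from .io_core import ConditionProtocol, RoiSet, ThreeCubeStack

log = logging.getLogger(__name__)


@dataclass
class FretMap:
    """Pixel-wise corrected FRET with a validity mask.

    Invalid pixels carry NaN (never 0 — a corrected FRET of zero is a
    meaningful value).
    """

    cfret: np.ndarray
    valid: np.ndarray
    factors_used: CorrectionFactors
    params_used: ProcessingParams


@dataclass
class FretTimeCourse:
    """Per-cell corrected-FRET trace with condition labels.

    ``cfret_norm`` is percent of the baseline mean (100 = baseline) and is
    defined only after :func:`normalize_to_baseline`.
    """

    cell_id: str
    t_s: np.ndarray
    cfret_raw: np.ndarray
    n_valid: np.ndarray
    condition: list
    cfret_norm: np.ndarray | None = None
    baseline_mean: float | None = None


def cfret_pixel(i_da, i_dd, i_aa, factors: CorrectionFactors):
    """The corrected-FRET quotient ``(I_DA - beta*I_DD - gamma*I_AA)/I_AA``.

    Accepts scalars or arrays; ``i_aa <= 0`` yields NaN (undefined pixel,
    invalid upstream).  Values are not clipped — noise can make them
    negative, and clipping would bias ROI means.
    """
    i_da = np.asarray(i_da, dtype=float)
    i_dd = np.asarray(i_dd, dtype=float)
    i_aa = np.asarray(i_aa, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (i_da - factors.beta * i_dd - factors.gamma * i_aa) / i_aa
    out = np.where(i_aa > 0, out, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def _process_frame(frame, params: ProcessingParams, background_level,
                   background_mask, background_method: str):
    """Background-subtract and blur the three channels of one time point."""
    processed, sds = [], []
    for img in frame:
        if background_method == "rolling_ball":
            _, sub = rolling_ball_subtract(img, params.rolling_ball_radius_px)
        else:
            # constant offset, unclipped: clipping would rectify background
            # noise into a positive offset that defeats sd-thresholding
            sub = img - (background_level or 0.0)
        blurred = gaussian_blur(sub, params.gaussian_sigma_px)
        processed.append(blurred)
        sds.append(estimate_background_sd(blurred, background_mask,
                                          params.rolling_ball_radius_px))
    return processed, sds


def cfret_map(frame, factors: CorrectionFactors,
              params: ProcessingParams | None = None,
              saturation_level: float = 65535.0,
              background_level: float | None = None,
              background_mask: np.ndarray | None = None,
              background_method: str = "offset") -> FretMap:
    """Corrected-FRET map of one three-channel frame.

    ``frame`` is the ``(i_dd, i_da, i_aa)`` triple of one time point.  Each
    channel is background-subtracted (constant offset or rolling ball) and
    Gaussian-blurred; pixels failing the validity mask (signal below
    ``threshold`` background sds in any channel, or saturated) are NaN.
    """
    params = params or ProcessingParams()
    processed, sds = _process_frame(frame, params, background_level,
                                    background_mask, background_method)
    valid = validity_mask(processed, frame, params, saturation_level, sds)
    if not valid.any():
        log.warning("cfret_map: all pixels invalid in this frame")
    p_dd, p_da, p_aa = processed
    cf = np.full(p_dd.shape, np.nan)
    cf[valid] = cfret_pixel(p_da[valid], p_dd[valid], p_aa[valid], factors)
    return FretMap(cfret=cf, valid=valid & np.isfinite(cf),
                   factors_used=factors, params_used=params)


def roi_timecourse(stack: ThreeCubeStack, rois: RoiSet,
                   factors: CorrectionFactors,
                   params: ProcessingParams | None = None,
                   protocol: ConditionProtocol | None = None,
                   background_level: float | None = None,
                   background_mask: np.ndarray | None = None,
                   background_method: str = "offset",
                   drop_missing_frac: float = 0.5) -> list:
    """Per-cell mean corrected FRET over time.

    For each ROI of kind ``cell``, ``cfret_raw(t)`` is the mean of the
    corrected-FRET map over ROI-intersect-valid pixels; condition labels are
    attached from the protocol.  Cells with zero valid pixels at more than
    ``drop_missing_frac`` of time points are dropped with a log entry.
    """
    params = params or ProcessingParams()
    cell_rois = rois.of_kind("cell")
    if not cell_rois:
        return []
    maps = [cfret_map(stack.frame(t), factors, params, stack.saturation_level,
                      background_level, background_mask, background_method)
            for t in range(stack.n_timepoints)]
    conditions = (protocol.labels_for(stack.timestamps) if protocol is not None
                  else [""] * stack.n_timepoints)
    out = []
    for roi in cell_rois:
        vals, nv = [], []
        for m in maps:
            v, n = roi_reduce(m.cfret, roi.mask, m.valid[None], "mean")
            vals.append(v)
            nv.append(n)
        vals = np.asarray(vals)
        nv = np.asarray(nv)
        if np.mean(nv == 0) > drop_missing_frac:
            log.warning("cell %s dropped: no valid pixels at >%d%% of time points",
                        roi.roi_id, int(100 * drop_missing_frac))
            continue
        out.append(FretTimeCourse(cell_id=roi.roi_id,
                                  t_s=np.asarray(stack.timestamps, dtype=float),
                                  cfret_raw=vals, n_valid=nv,
                                  condition=list(conditions)))
    return out


def normalize_to_baseline(tc: FretTimeCourse,
                          baseline_condition: str = "iso") -> FretTimeCourse:
    """Normalize a trace to its baseline-condition mean, in percent.

    The baseline window is every time point carrying the baseline condition
    *before the first condition switch* (initial isotonic period only, not
    later returns to baseline).  Requires >= 3 baseline points and a positive
    baseline mean.
    """
    labels = tc.condition
    idx = []
    for i, lab in enumerate(labels):
        if lab == baseline_condition:
            idx.append(i)
        else:
            break
    if len(idx) < 3:
        raise NormalizationError(
            f"baseline window has {len(idx)} points (< 3) before the first switch")
    base = float(np.nanmean(tc.cfret_raw[idx]))
    if not np.isfinite(base) or base <= 0:
        raise NormalizationError(f"baseline mean {base} is not positive")
    tc.cfret_norm = 100.0 * tc.cfret_raw / base
    tc.baseline_mean = base
    return tc


def condition_window_mean(tc: FretTimeCourse, condition: str,
                          which: str = "last_k", k: int = 3,
                          use: str = "norm", max_t_s: float | None = None) -> float:
    """Mean normalized cFRET over the first/last ``k`` points of a condition.

    This is the figure-legend convention (e.g. first 7 isotonic / last 3
    hypotonic points).  ``max_t_s`` optionally restricts the window to time
    points at or before an absolute time.  If fewer than ``k`` points exist,
    all available are used with a warning.
    """
    if which not in ("first_k", "last_k"):
        raise WindowError(f"unknown window spec {which!r}")
    y = tc.cfret_norm if use == "norm" else tc.cfret_raw
    if y is None:
        raise WindowError("trace not normalized; call normalize_to_baseline first")
    idx = [i for i, lab in enumerate(tc.condition) if lab == condition]
    if max_t_s is not None:
        idx = [i for i in idx if tc.t_s[i] <= max_t_s + 1e-9]
    if not idx:
        raise WindowError(f"condition {condition!r} absent from trace")
    if len(idx) < k:
        log.warning("window asked for %d points, only %d available", k, len(idx))
        chosen = idx
    else:
        chosen = idx[:k] if which == "first_k" else idx[-k:]
    return float(np.nanmean(y[chosen]))
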