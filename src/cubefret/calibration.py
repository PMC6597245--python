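"""Spectral correction-factor estimation from single-label samples.

``beta`` (donor emission bleeding into the FRET channel) is estimated from
donor-only stacks as the proportionality between I_DA and I_DD; ``gamma``
(direct acceptor excitation by donor-excitation light) symmetrically from
acceptor-only stacks as I_DA vs I_AA.  Per-FOV estimates are pooled by
averaging across fields of view measured on several days (3 days x 3 FOVs in
the standard design).

Estimators
----------
``ratio_mean``
    Mean over valid pixels of the per-pixel intensity ratio (the PixFRET
    convention).

``regression_slope`` (default)
    Least-squares slope through the origin with inverse-variance (shot
    noise) weights, algebraically the ratio of summed intensities
    ``sum(I_DA) / sum(I_DD)``.  Unlike the unweighted through-origin slope,
    this is robust to intensity-dependent noise: noise in the regressor
    attenuates the unweighted slope by roughly one part per mean count,
    while the weighted form is unbiased to O(1/total counts).

Both reduce to the exact crosstalk factor on noiseless homogeneous data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import EstimationError, ParameterError
from .imageops import ProcessingParams, estimate_background_sd, gaussian_blur
from .io_core import ThreeCubeStack

log = logging.getLogger(__name__)

METHODS = ("ratio_mean", "regression_slope")


@dataclass
class CorrectionFactors:
    """Calibrated spectral correction state used by the cFRET equation."""

    beta: float
    gamma: float
    beta_sd: float = 0.0
    gamma_sd: float = 0.0
    n_fovs: int = 1
    n_days: int = 1
    method: str = "regression_slope"

    def __post_init__(self):
        if self.beta <= 0 or self.gamma <= 0:
            raise EstimationError("beta and gamma must be positive")
        if self.beta_sd < 0 or self.gamma_sd < 0 or not np.isfinite(self.beta_sd + self.gamma_sd):
            raise EstimationError("factor sds must be finite and non-negative")


DENOMINATOR_FLOOR_SDS = 3.0


def _single_label_estimate(numerator: np.ndarray, denominator: np.ndarray,
                           raw_channels, params: ProcessingParams,
                           saturation_level: float, method: str,
                           background_mask: np.ndarray | None,
                           min_valid: int) -> float:
    """One-FOV crosstalk factor from processed numerator/denominator images.

    The regressor (denominator) must clear a 3-sd background floor — the
    same convention as the ratio-map denominator floor — so that pure
    background pixels, whose ratio is noise, cannot dilute the estimate.
    """
    sd = estimate_background_sd(denominator, background_mask,
                                params.rolling_ball_radius_px)
    valid = denominator > max(params.threshold, DENOMINATOR_FLOOR_SDS) * sd
    ceiling = params.saturation_margin * saturation_level
    for raw in raw_channels:
        valid &= np.asarray(raw, dtype=float) < ceiling
    x = denominator[valid]
    y = numerator[valid]
    finite = np.isfinite(x) & np.isfinite(y) & (x > 0)
    n_dropped = int(valid.sum() - finite.sum())
    if n_dropped:
        log.info("calibration: excluded %d non-finite/non-positive pixels", n_dropped)
    x, y = x[finite], y[finite]
    if x.size < min_valid:
        raise EstimationError(
            f"only {x.size} valid pixels (< {min_valid}) for calibration")
    if method == "ratio_mean":
        return float(np.mean(y / x))
    if method == "regression_slope":
        # inverse-variance weighted LS through the origin == ratio of sums
        return float(np.sum(y) / np.sum(x))
    raise ParameterError(f"unknown calibration method {method!r}")


def _prepare(stack: ThreeCubeStack, params: ProcessingParams,
             background_level: float | None):
    """Background-subtract and blur the first frame of a calibration stack.

    Subtraction is not clipped at zero: clipping rectifies zero-mean
    background noise into a positive offset that biases ratio estimators.
    """
    i_dd, i_da, i_aa = stack.frame(0)
    if background_level is None:
        background_level = 0.0
    out = [gaussian_blur(img - background_level, params.gaussian_sigma_px)
           for img in (i_dd, i_da, i_aa)]
    return out, (i_dd, i_da, i_aa)


def estimate_beta(donor_only, params: ProcessingParams | None = None,
                  method: str = "regression_slope",
                  background_level: float | None = None,
                  background_masks=None, min_valid: int = 100,
                  purity_ceiling_sd: float = 2.0):
    """Per-FOV and pooled donor bleed-through ``beta``.

    ``donor_only`` is a sequence of single-time-point ThreeCubeStacks from
    donor-only samples.  Validity uses the donor channel (the regressor) plus
    saturation checks; a FOV whose median acceptor signal exceeds
    ``purity_ceiling_sd`` background sds triggers a purity warning.

    Returns ``(per_fov, pooled_mean, pooled_sd)``.
    """
    params = params or ProcessingParams()
    per_fov = []
    for i, stack in enumerate(donor_only):
        mask = None if background_masks is None else background_masks[i]
        (p_dd, p_da, p_aa), raw = _prepare(stack, params, background_level)
        # purity on the unclipped raw channel: clipping rectifies noise upward
        excess = float(np.median(raw[2]) - (background_level or 0.0))
        aa_sd = estimate_background_sd(raw[2], mask, params.rolling_ball_radius_px)
        if excess > purity_ceiling_sd * max(aa_sd, 1e-12):
            log.warning("donor-only FOV %d shows acceptor signal; purity suspect", i)
        per_fov.append(_single_label_estimate(
            p_da, p_dd, (raw[0], raw[1]), params, stack.saturation_level,
            method, mask, min_valid))
    per_fov = np.asarray(per_fov)
    if len(per_fov) > 1:
        return per_fov, float(np.mean(per_fov)), float(np.std(per_fov, ddof=1))
    return per_fov, float(np.mean(per_fov)), 0.0


def estimate_gamma(acceptor_only, params: ProcessingParams | None = None,
                   method: str = "regression_slope",
                   background_level: float | None = None,
                   background_masks=None, min_valid: int = 100,
                   purity_ceiling_sd: float = 2.0):
    """Per-FOV and pooled acceptor cross-excitation ``gamma`` (I_DA vs I_AA)."""
    params = params or ProcessingParams()
    per_fov = []
    for i, stack in enumerate(acceptor_only):
        mask = None if background_masks is None else background_masks[i]
        (p_dd, p_da, p_aa), raw = _prepare(stack, params, background_level)
        excess = float(np.median(raw[0]) - (background_level or 0.0))
        dd_sd = estimate_background_sd(raw[0], mask, params.rolling_ball_radius_px)
        if excess > purity_ceiling_sd * max(dd_sd, 1e-12):
            log.warning("acceptor-only FOV %d shows donor signal; purity suspect", i)
        per_fov.append(_single_label_estimate(
            p_da, p_aa, (raw[2], raw[1]), params, stack.saturation_level,
            method, mask, min_valid))
    per_fov = np.asarray(per_fov)
    if len(per_fov) > 1:
        return per_fov, float(np.mean(per_fov)), float(np.std(per_fov, ddof=1))
    return per_fov, float(np.mean(per_fov)), 0.0


def pool_calibration(beta_per_fov, gamma_per_fov, day_labels=None,
                     method: str = "regression_slope") -> CorrectionFactors:
    """Pool per-FOV estimates into a :class:`CorrectionFactors`.

    Pooled value is the mean of per-FOV estimates, its sd their sample sd
    (0 for a single FOV); day-level means are logged when labels are given.
    """
    beta_per_fov = np.asarray(beta_per_fov, dtype=float)
    gamma_per_fov = np.asarray(gamma_per_fov, dtype=float)
    if beta_per_fov.size < 1 or gamma_per_fov.size < 1:
        raise EstimationError("need at least one FOV")
    n_fovs = int(beta_per_fov.size)
    if day_labels is not None:
        days = np.asarray(day_labels)
        n_days = int(len(np.unique(days)))
        for d in np.unique(days):
            log.info("calibration day %s: beta=%.4f gamma=%.4f", d,
                     beta_per_fov[days == d].mean(), gamma_per_fov[days == d].mean())
    else:
        n_days = 1
    sd = lambda v: float(np.std(v, ddof=1)) if v.size > 1 else 0.0
    return CorrectionFactors(
        beta=float(beta_per_fov.mean()), gamma=float(gamma_per_fov.mean()),
        beta_sd=sd(beta_per_fov), gamma_sd=sd(gamma_per_fov),
        n_fovs=n_fovs, n_days=n_days, method=method)
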