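"""Patch-clamp-fluorometry co-analysis.

Extracts per-episode steady-state currents from episodic voltage-protocol
recordings (0.5 s steps to -80 mV every 12 s in the standard protocol),
normalizes to cell capacitance, fits single-exponential activation/recovery
kinetics, and compares current kinetics with FRET time-course kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .errors import (AlignmentError, FitError, ParameterError, StatisticsError,
                     ValidationError)


@dataclass
class CurrentTrace:
    """Episodic whole-cell current recording with protocol timing.

    ``episodes`` is a table with columns
    ``episode_index, t_start_s, v_step_mv, duration_s``.
    """

    t_s: np.ndarray
    i_pa: np.ndarray
    v_mv: np.ndarray
    episodes: pd.DataFrame
    capacitance_pf: float | None = None

    def __post_init__(self):
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.i_pa = np.asarray(self.i_pa, dtype=float)
        self.v_mv = np.asarray(self.v_mv, dtype=float)
        if not (len(self.t_s) == len(self.i_pa) == len(self.v_mv)):
            raise ValidationError("t_s, i_pa, v_mv must have equal length")
        ep = self.episodes.sort_values("t_start_s")
        ends = ep["t_start_s"].to_numpy() + ep["duration_s"].to_numpy()
        if np.any(ends[:-1] > ep["t_start_s"].to_numpy()[1:] + 1e-12):
            raise ValidationError("episodes must not overlap")
        self.episodes = ep.reset_index(drop=True)


@dataclass
class KineticsFit:
    """Single-exponential fit ``y = offset + amplitude * exp(-(t-t0)/tau)``."""

    amplitude: float
    tau_s: float
    offset: float
    rmse: float
    t0_s: float
    window: tuple = field(default=(0.0, 0.0))

    def __post_init__(self):
        if self.tau_s <= 0:
            raise ValidationError("tau must be positive")
        if self.rmse < 0:
            raise ValidationError("rmse must be >= 0")


def episode_currents(trace: CurrentTrace, v_select_mv: float = -80.0,
                     window_frac: tuple = (0.5, 0.9)):
    """Steady-state current per qualifying episode.

    For each episode at ``v_select_mv``, the mean current over the fractional
    window of the step (default 50-90%, avoiding capacitive transients) is
    reported at the episode's window-center time.

    Returns ``(times_s, currents_pa)`` arrays, one entry per episode.
    """
    sel = trace.episodes[np.isclose(trace.episodes["v_step_mv"], v_select_mv)]
    if len(sel) == 0:
        raise ParameterError(f"no episodes at {v_select_mv} mV")
    lo, hi = window_frac
    if not (0 <= lo < hi <= 1):
        raise ParameterError("window_frac must satisfy 0 <= lo < hi <= 1")
    times, currents = [], []
    for ep in sel.itertuples():
        t0 = ep.t_start_s + lo * ep.duration_s
        t1 = ep.t_start_s + hi * ep.duration_s
        in_win = (trace.t_s >= t0) & (trace.t_s <= t1)
        if not np.any(in_win):
            continue
        times.append(0.5 * (t0 + t1))
        currents.append(float(np.mean(trace.i_pa[in_win])))
    return np.asarray(times), np.asarray(currents)


def current_density(current_pa: float | np.ndarray,
                    capacitance_pf: float | None):
    """Current normalized to cell capacitance, in pA/pF."""
    if capacitance_pf is None:
        raise ParameterError("capacitance missing; cannot compute current density")
    if capacitance_pf <= 0:
        raise ParameterError("capacitance must be positive")
    return np.asarray(current_pa, dtype=float) / capacitance_pf


def _exp_model(t, offset, amplitude, tau):
    return offset + amplitude * np.exp(-t / tau)


def fit_exponential(t_s, y, direction: str = "onset",
                    max_restarts: int = 5, seed: int = 0,
                    rmse_flag_frac: float = 0.15) -> KineticsFit:
    """Least-squares single-exponential fit of a post-switch segment.

    Deterministic initialization: offset = last value, amplitude = first -
    last, tau = one-third of the segment span; on failure, bounded restarts
    with seeded jitter.  ``direction`` is bookkeeping only (onset vs
    recovery); the model is the same.  A fit whose rmse exceeds
    ``rmse_flag_frac * |amplitude|`` is flagged (``rmse`` is always reported).
    """
    t_s = np.asarray(t_s, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(t_s) & np.isfinite(y)
    t_s, y = t_s[ok], y[ok]
    if len(y) < 6:
        raise FitError("need >= 6 points for an exponential fit")
    if direction not in ("onset", "recovery"):
        raise ParameterError("direction must be 'onset' or 'recovery'")
    t0 = t_s[0]
    tt = t_s - t0
    span = tt[-1] if tt[-1] > 0 else 1.0
    p0 = np.array([y[-1], y[0] - y[-1], span / 3.0])
    rng = np.random.default_rng(seed)
    last_exc = None
    for attempt in range(max_restarts + 1):
        init = p0 if attempt == 0 else p0 * (1 + 0.3 * rng.standard_normal(3))
        init[2] = abs(init[2]) or span / 3.0
        try:
            popt, _ = curve_fit(_exp_model, tt, y, p0=init, maxfev=5000,
                                bounds=([-np.inf, -np.inf, 1e-9],
                                        [np.inf, np.inf, np.inf]))
        except (RuntimeError, ValueError) as exc:
            last_exc = exc
            continue
        resid = y - _exp_model(tt, *popt)
        rmse = float(np.sqrt(np.mean(resid ** 2)))
        return KineticsFit(amplitude=float(popt[1]), tau_s=float(popt[2]),
                           offset=float(popt[0]), rmse=rmse, t0_s=float(t0),
                           window=(float(t_s[0]), float(t_s[-1])))
    raise FitError(f"exponential fit did not converge after {max_restarts} restarts: "
                   f"{last_exc}")


def co_kinetics(fret_t_s, fret_y, current_t_s, current_y,
                direction: str = "onset", n_grid: int = 50) -> dict:
    """Compare FRET and current kinetics on their overlapping support.

    Fits a single exponential to each series, reports both time constants,
    their ratio (tau_fret / tau_current), and the Pearson correlation of the
    two series linearly resampled onto a common time grid.
    """
    fret_t_s = np.asarray(fret_t_s, dtype=float)
    current_t_s = np.asarray(current_t_s, dtype=float)
    lo = max(fret_t_s.min(), current_t_s.min())
    hi = min(fret_t_s.max(), current_t_s.max())
    if hi <= lo:
        raise AlignmentError("FRET and current series do not overlap in time")
    fit_f = fit_exponential(fret_t_s, np.asarray(fret_y, float), direction)
    fit_c = fit_exponential(current_t_s, np.asarray(current_y, float), direction)
    grid = np.linspace(lo, hi, n_grid)
    f_rs = np.interp(grid, fret_t_s, fret_y)
    c_rs = np.interp(grid, current_t_s, current_y)
    if np.std(f_rs) == 0 or np.std(c_rs) == 0:
        r, flat = 0.0, True
    else:
        r = float(pearsonr(f_rs, c_rs)[0])
        flat = False
    return {
        "tau_fret_s": fit_f.tau_s,
        "tau_current_s": fit_c.tau_s,
        "tau_ratio": fit_f.tau_s / fit_c.tau_s,
        "pearson_r": r,
        "degenerate_series": flat,
        "fret_fit": fit_f,
        "current_fit": fit_c,
    }
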