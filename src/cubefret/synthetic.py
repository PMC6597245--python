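"""Forward simulation of three-cube FRET experiments with known ground truth.

The generator emulates the standard swelling-activation experiment: blob
shaped cells with per-cell log-normal donor/acceptor expression, a FRET
efficiency that relaxes first-order toward a condition-dependent target on a
~90 s timescale when the buffer switches (isotonic -> hypotonic), spectral
mixing with fixed bleed-through ``beta`` and cross-excitation ``gamma``,
Poisson shot noise plus Gaussian read noise and a constant background level,
detector saturation clipping, and optional per-frame photobleaching.

Noiseless pixel model at one time point, for a pixel with donor
concentration ``d``, acceptor concentration ``a`` and efficiency ``E``::

    I_DD = k_D * d * (1 - E) + bg
    I_AA = k_A * a + bg
    I_DA = k_S * d * E + beta * (I_DD - bg) + gamma * (I_AA - bg) + bg

so that after perfect background subtraction the corrected-FRET quotient
``(I_DA - beta*I_DD - gamma*I_AA) / I_AA`` equals ``k_S*d*E / (k_A*a)``
exactly — the sensitized emission is additive on top of the crosstalk terms,
the minimal model under which the correction equation is exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, PlacementError, ValidationError
from .io_core import ConditionProtocol, ThreeCubeStack
from .pcf import CurrentTrace


@dataclass
class ActivationKinetics:
    """First-order relaxation of FRET efficiency toward condition targets.

    ``e_rest`` is the baseline (isotonic) efficiency, ``delta_e`` the signed
    change in the activating (hypotonic) condition; relaxation uses
    ``tau_on_s`` toward an activated target and ``tau_off_s`` back toward
    rest.  Defaults give an ~10% relative efficiency drop with ~90 s
    near-completion, matching the headline swelling phenomenology.
    """

    tau_on_s: float = 30.0
    tau_off_s: float = 45.0
    e_rest: float = 0.30
    delta_e: float = -0.03

    def __post_init__(self):
        if not (0 < self.e_rest < 1):
            raise ValidationError("e_rest must be in (0, 1)")
        if not (0 <= self.e_rest + self.delta_e < 1):
            raise ValidationError("e_rest + delta_e must be in [0, 1)")
        if self.tau_on_s <= 0 or self.tau_off_s <= 0:
            raise ValidationError("time constants must be positive")


@dataclass
class Brightness:
    """Channel gains: donor (k_D), acceptor (k_A), sensitized emission (k_S)."""

    k_d: float = 1.0
    k_a: float = 1.0
    k_s: float = 1.0

    def __post_init__(self):
        if min(self.k_d, self.k_a, self.k_s) <= 0:
            raise ValidationError("brightness gains must be positive")


@dataclass
class NoiseModel:
    poisson_enabled: bool = True
    read_sd: float = 2.0
    background_level: float = 20.0

    def __post_init__(self):
        if self.read_sd < 0 or self.background_level < 0:
            raise ValidationError("noise parameters must be non-negative")


@dataclass
class GroundTruth:
    """Hidden state of a simulated experiment — the test oracle."""

    donor_map: np.ndarray
    acceptor_map: np.ndarray
    efficiency: np.ndarray           # (T, n_cells)
    beta_true: float
    gamma_true: float
    brightness: Brightness
    noise: NoiseModel
    bleach_rates: tuple = (0.0, 0.0, 0.0)   # per-frame fractional decay per channel
    cell_labels: np.ndarray = None
    donor_levels: np.ndarray = None          # per-cell expression scalars
    acceptor_levels: np.ndarray = None
    seed: int = 0

    def __post_init__(self):
        if np.any(self.efficiency < 0) or np.any(self.efficiency >= 1):
            raise ValidationError("efficiency must be in [0, 1)")
        if np.any(self.donor_map < 0) or np.any(self.acceptor_map < 0):
            raise ValidationError("concentration maps must be non-negative")
        if self.beta_true <= 0 or self.gamma_true <= 0:
            raise ValidationError("beta_true and gamma_true must be positive")

    @property
    def n_cells(self) -> int:
        return self.efficiency.shape[1]

    def analytic_cfret(self) -> np.ndarray:
        """Expected corrected-FRET per cell per time point, (T, n_cells).

        At a background-free pixel after perfect background subtraction the
        corrected quotient equals ``k_S*d*E / (k_A*a)``; with per-cell
        uniform expression this is a per-cell scalar.
        """
        b = self.brightness
        ratio = b.k_s * self.donor_levels / (b.k_a * self.acceptor_levels)
        return self.efficiency * ratio[None, :]


DEFAULT_SHAPE = (96, 96)
DEFAULT_EXPRESSION_MEAN = 800.0
DEFAULT_EXPRESSION_SIGMA = 0.5     # log-normal sd across cells
DEFAULT_BETA = 0.60
DEFAULT_GAMMA = 0.15
DEFAULT_CELL_SD = 0.05             # relative per-cell kinetics variability
SATURATION = 65535.0


def make_cell_field(n_cells: int, shape=DEFAULT_SHAPE, seed: int = 0,
                    radius_px: float = 11.0, min_gap_px: float = 18.0,
                    expression_mean: float = DEFAULT_EXPRESSION_MEAN,
                    expression_sigma: float = DEFAULT_EXPRESSION_SIGMA,
                    max_retries: int = 200, max_field_retries: int = 20):
    """Place blob-shaped cells with per-cell log-normal expression.

    Returns ``(cell_labels, donor_map, acceptor_map, donor_levels,
    acceptor_levels)``.  Expression is uniform within a cell (donor and
    acceptor drawn independently per cell, mimicking variable expression
    ratios); background pixels are labeled 0 and carry zero concentration.
    Cells are separated by at least ``min_gap_px`` so that later smoothing
    never mixes two cells.
    """
    if n_cells < 1:
        raise ParameterError("n_cells must be >= 1")
    h, w = shape
    rng = np.random.default_rng(seed)
    margin = radius_px * 1.3 + 1
    # rejection placement; a stuck configuration restarts the whole field
    centers = None
    for _ in range(max_field_retries):
        trial = []
        ok = True
        for _ in range(n_cells):
            for attempt in range(max_retries):
                c = rng.uniform([margin, margin], [h - margin, w - margin])
                if all(np.hypot(*(c - np.asarray(o))) >= 2 * radius_px + min_gap_px
                       for o in trial):
                    trial.append(c)
                    break
            else:
                ok = False
                break
        if ok:
            centers = trial
            break
    if centers is None:
        raise PlacementError(
            f"could not place {n_cells} cells of radius {radius_px} in {shape}")
    labels = np.zeros(shape, dtype=int)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, (cy, cx) in enumerate(centers, start=1):
        # smooth blob: radius modulated by a low-order Fourier perturbation
        phase = rng.uniform(0, 2 * np.pi, size=3)
        amp = rng.uniform(0.05, 0.15, size=3)
        theta = np.arctan2(yy - cy, xx - cx)
        r_theta = radius_px * (1 + sum(a * np.cos((k + 2) * theta + p)
                                       for k, (a, p) in enumerate(zip(amp, phase))))
        inside = np.hypot(yy - cy, xx - cx) <= r_theta
        labels[inside] = i
    donor_levels = expression_mean * rng.lognormal(0.0, expression_sigma, n_cells)
    acceptor_levels = expression_mean * rng.lognormal(0.0, expression_sigma, n_cells)
    donor_map = np.zeros(shape)
    acceptor_map = np.zeros(shape)
    for i in range(1, n_cells + 1):
        donor_map[labels == i] = donor_levels[i - 1]
        acceptor_map[labels == i] = acceptor_levels[i - 1]
    return labels, donor_map, acceptor_map, donor_levels, acceptor_levels


def simulate_efficiency(protocol: ConditionProtocol, kinetics: ActivationKinetics,
                        timestamps, n_cells: int, cell_sd: float = DEFAULT_CELL_SD,
                        seed: int = 0, condition_targets: dict | None = None) -> np.ndarray:
    """Per-cell FRET efficiency time course under a condition protocol.

    E relaxes exponentially toward the current condition's target (``e_rest``
    for the baseline condition, ``e_rest + delta_e`` for the activating one by
    default; overridable per label via ``condition_targets`` offsets from
    rest).  Per-cell variability multiplies ``e_rest`` and ``delta_e`` by
    independent ``1 + N(0, cell_sd)`` factors.  Returns a (T, n_cells) array.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if timestamps.min() < protocol.start_s or timestamps.max() > protocol.end_s:
        raise ValidationError("protocol must cover all timestamps")
    rng = np.random.default_rng(seed)
    out = np.empty((len(timestamps), n_cells))
    for c in range(n_cells):
        f_rest = 1 + cell_sd * rng.standard_normal()
        f_delta = 1 + cell_sd * rng.standard_normal()
        e_rest_c = float(np.clip(kinetics.e_rest * f_rest, 1e-3, 0.95))
        delta_c = kinetics.delta_e * f_delta
        if condition_targets is None:
            targets = {}
        else:
            targets = {k: e_rest_c + v for k, v in condition_targets.items()}

        def target_of(cond):
            if cond in targets:
                return targets[cond]
            if cond == "hypo":
                return float(np.clip(e_rest_c + delta_c, 0.0, 0.99))
            return e_rest_c

        # exact piecewise-exponential stepping through segment boundaries,
        # starting at steady state in the first segment's condition
        e = target_of(protocol.segments[0].condition)
        t_prev = protocol.start_s
        ti = 0
        for seg in protocol.segments:
            tgt = target_of(seg.condition)
            tau = kinetics.tau_off_s if np.isclose(tgt, e_rest_c) else kinetics.tau_on_s
            while ti < len(timestamps) and timestamps[ti] <= seg.end_s + 1e-9:
                t = timestamps[ti]
                if t < seg.start_s - 1e-9:
                    ti += 1
                    continue
                e_t = tgt + (e - tgt) * np.exp(-(t - t_prev) / tau)
                out[ti, c] = e_t
                ti += 1
                e, t_prev = e_t, t
            # advance internal state to the segment end
            e = tgt + (e - tgt) * np.exp(-(seg.end_s - t_prev) / tau)
            t_prev = seg.end_s
    return np.clip(out, 0.0, 0.999)


def _efficiency_map(truth: GroundTruth, t_index: int) -> np.ndarray:
    e_map = np.zeros_like(truth.donor_map)
    for c in range(truth.n_cells):
        e_map[truth.cell_labels == c + 1] = truth.efficiency[t_index, c]
    return e_map


def _render_frame(d_map, a_map, e_map, truth: GroundTruth, frame_index: int,
                  rng: np.random.Generator | None):
    b, nz = truth.brightness, truth.noise
    bg = nz.background_level
    decay = [(1.0 - r) ** frame_index for r in truth.bleach_rates]
    sig_dd = b.k_d * d_map * (1.0 - e_map) * decay[0]
    sig_aa = b.k_a * a_map * decay[2]
    # the FRET channel carries one per-frame decay factor of its own
    sig_da = (b.k_s * d_map * e_map
              + truth.beta_true * b.k_d * d_map * (1.0 - e_map)
              + truth.gamma_true * b.k_a * a_map) * decay[1]
    frames = []
    for sig in (sig_dd, sig_da, sig_aa):
        img = sig + bg
        if rng is not None and nz.poisson_enabled:
            img = rng.poisson(img).astype(float)
        if rng is not None and nz.read_sd > 0:
            img = img + nz.read_sd * rng.standard_normal(img.shape)
        frames.append(np.clip(img, 0.0, SATURATION))
    return frames


def render_three_cube(truth: GroundTruth, timestamps) -> ThreeCubeStack:
    """Render a full three-channel stack from ground truth.

    Noise (Poisson then Gaussian read noise) and saturation clipping are
    applied iff enabled in ``truth.noise``; with noise off and zero
    background the render is the exact noiseless pixel model.
    """
    timestamps = np.asarray(timestamps, dtype=float)
    if len(timestamps) != truth.efficiency.shape[0]:
        raise ValidationError("timestamps length must match efficiency rows")
    noisy = truth.noise.poisson_enabled or truth.noise.read_sd > 0
    rng = np.random.default_rng(truth.seed + 1) if noisy else None
    dd, da, aa = [], [], []
    for t in range(len(timestamps)):
        e_map = _efficiency_map(truth, t)
        f_dd, f_da, f_aa = _render_frame(truth.donor_map, truth.acceptor_map,
                                         e_map, truth, t, rng)
        dd.append(f_dd)
        da.append(f_da)
        aa.append(f_aa)
    return ThreeCubeStack(i_dd=np.stack(dd), i_da=np.stack(da), i_aa=np.stack(aa),
                          timestamps=timestamps, saturation_level=SATURATION)


def default_ground_truth(n_cells: int = 3, shape=DEFAULT_SHAPE, seed: int = 0,
                         protocol: ConditionProtocol | None = None,
                         timestamps=None,
                         kinetics: ActivationKinetics | None = None,
                         noise: NoiseModel | None = None,
                         beta_true: float = DEFAULT_BETA,
                         gamma_true: float = DEFAULT_GAMMA,
                         cell_sd: float = DEFAULT_CELL_SD,
                         condition_targets: dict | None = None):
    """Assemble a complete default experiment: truth, protocol, timestamps."""
    from .io_core import default_protocol
    if protocol is None:
        protocol = default_protocol()
    if timestamps is None:
        timestamps = np.arange(protocol.start_s, protocol.end_s + 1e-9, 10.0)
    kinetics = kinetics or ActivationKinetics()
    noise = noise or NoiseModel()
    labels, d_map, a_map, d_lvl, a_lvl = make_cell_field(n_cells, shape, seed)
    eff = simulate_efficiency(protocol, kinetics, timestamps, n_cells,
                              cell_sd=cell_sd, seed=seed + 10,
                              condition_targets=condition_targets)
    truth = GroundTruth(donor_map=d_map, acceptor_map=a_map, efficiency=eff,
                        beta_true=beta_true, gamma_true=gamma_true,
                        brightness=Brightness(), noise=noise,
                        cell_labels=labels, donor_levels=d_lvl,
                        acceptor_levels=a_lvl, seed=seed)
    return truth, protocol, np.asarray(timestamps, dtype=float)


def make_calibration_stacks(n_days: int = 3, n_fovs_per_day: int = 3,
                            n_cells: int = 3, shape=DEFAULT_SHAPE, seed: int = 0,
                            beta_true: float = DEFAULT_BETA,
                            gamma_true: float = DEFAULT_GAMMA,
                            noise: NoiseModel | None = None):
    """Donor-only and acceptor-only calibration fields-of-view.

    Mirrors the standard calibration design: single-label samples measured on
    ``n_days`` days with ``n_fovs_per_day`` FOVs each.  Donor-only stacks have
    zero acceptor (and hence E = 0, so ``I_DA = beta*I_DD`` + background
    terms); acceptor-only stacks have zero donor (``I_DA = gamma*I_AA`` +
    background terms).

    Returns two lists of ``(day_index, ThreeCubeStack, GroundTruth)``.
    """
    if n_fovs_per_day < 1 or n_days < 1:
        raise ParameterError("need at least one day and one FOV per day")
    noise = noise or NoiseModel()
    donor_only, acceptor_only = [], []
    fov_seed = seed
    for day in range(n_days):
        for _ in range(n_fovs_per_day):
            for which, out in (("donor", donor_only), ("acceptor", acceptor_only)):
                fov_seed += 1
                labels, d_map, a_map, d_lvl, a_lvl = make_cell_field(
                    n_cells, shape, fov_seed)
                if which == "donor":
                    a_map, a_lvl = np.zeros_like(a_map), np.zeros_like(a_lvl)
                else:
                    d_map, d_lvl = np.zeros_like(d_map), np.zeros_like(d_lvl)
                eff = np.zeros((1, n_cells))
                truth = GroundTruth(donor_map=d_map, acceptor_map=a_map,
                                    efficiency=eff, beta_true=beta_true,
                                    gamma_true=gamma_true, brightness=Brightness(),
                                    noise=noise, cell_labels=labels,
                                    donor_levels=d_lvl, acceptor_levels=a_lvl,
                                    seed=fov_seed)
                stack = render_three_cube(truth, [0.0])
                out.append((day, stack, truth))
    return donor_only, acceptor_only


def simulate_bleach_experiment(truth: GroundTruth, bleach_mask: np.ndarray,
                               bleach_fraction: float, q: float = 1.0):
    """Pre/post stacks of an acceptor-photobleaching experiment.

    Inside ``bleach_mask`` the acceptor concentration is multiplied by
    ``1 - bleach_fraction`` in the post stack, and donor quenching follows the
    pixel model: donor intensity rises from ``k_D*d*(1-E)`` to
    ``k_D*d*(1 - E*(1-bleach_fraction)*q)`` where ``q`` is the fraction of
    donor quenching attributable to surviving acceptors (1 in the simple
    model).  Nothing changes outside the region.

    Returns ``(pre_stack, post_stack)`` single-time-point stacks.
    """
    if not (0 <= bleach_fraction <= 1):
        raise ValidationError("bleach_fraction must be in [0, 1]")
    bleach_mask = np.asarray(bleach_mask, dtype=bool)
    e_map = _efficiency_map(truth, 0)
    noisy = truth.noise.poisson_enabled or truth.noise.read_sd > 0
    rng_pre = np.random.default_rng(truth.seed + 100) if noisy else None
    rng_post = np.random.default_rng(truth.seed + 200) if noisy else None
    pre = _render_frame(truth.donor_map, truth.acceptor_map, e_map, truth, 0, rng_pre)
    a_post = truth.acceptor_map.copy()
    a_post[bleach_mask] *= (1.0 - bleach_fraction)
    e_post = e_map.copy()
    e_post[bleach_mask] *= (1.0 - bleach_fraction) * q
    post = _render_frame(truth.donor_map, a_post, e_post, truth, 0, rng_post)

    def pack(frames):
        return ThreeCubeStack(i_dd=frames[0][None], i_da=frames[1][None],
                              i_aa=frames[2][None], timestamps=[0.0],
                              saturation_level=SATURATION)
    return pack(pre), pack(post)


def simulate_current_trace(fret_t_s, efficiency_1cell, kinetics: ActivationKinetics,
                           g_max_ns: float = 10.0, t0_s: float = 0.0,
                           n_episodes: int | None = None,
                           episode_period_s: float = 12.0,
                           step_duration_s: float = 0.5,
                           v_step_mv: float = -80.0, v_hold_mv: float = -30.0,
                           sample_hz: float = 100.0, noise_sd_pa: float = 0.0,
                           capacitance_pf: float = 20.0,
                           seed: int = 0) -> CurrentTrace:
    """Episodic whole-cell current coupled instantaneously to the FRET state.

    Conductance is ``g_max_ns * clip((E(t) - e_rest)/delta_e, 0, 1)`` — zero
    at rest, ``g_max_ns`` at full activation — and current (pA) is
    conductance times command voltage (mV; reversal at 0 mV).  The protocol
    is the standard episodic one: ``step_duration_s`` steps to ``v_step_mv``
    every ``episode_period_s`` (9 episodes per repetition by default),
    repeated over the span of the FRET time course.
    """
    if kinetics.delta_e == 0 and g_max_ns != 0:
        raise ParameterError("delta_e = 0 with nonzero g_max: degenerate coupling")
    fret_t_s = np.asarray(fret_t_s, dtype=float)
    eff = np.asarray(efficiency_1cell, dtype=float)
    span = fret_t_s[-1] - t0_s
    if n_episodes is None:
        n_episodes = int(span // episode_period_s) + 1
    rng = np.random.default_rng(seed)
    ep_rows, t_all, i_all, v_all = [], [], [], []
    n_samp = max(int(step_duration_s * sample_hz), 2)
    for k in range(n_episodes):
        t_start = t0_s + k * episode_period_s
        if t_start + step_duration_s > fret_t_s[-1] + 1e-9:
            break
        ep_rows.append({"episode_index": k, "t_start_s": t_start,
                        "v_step_mv": v_step_mv, "duration_s": step_duration_s})
        ts = t_start + np.linspace(0, step_duration_s, n_samp, endpoint=False)
        e_t = np.interp(ts, fret_t_s, eff)
        act = np.clip((e_t - kinetics.e_rest) / kinetics.delta_e, 0.0, 1.0)
        i = g_max_ns * act * v_step_mv
        if noise_sd_pa > 0:
            i = i + noise_sd_pa * rng.standard_normal(i.shape)
        t_all.append(ts)
        i_all.append(i)
        v_all.append(np.full_like(ts, v_step_mv))
    episodes = pd.DataFrame(ep_rows)
    return CurrentTrace(t_s=np.concatenate(t_all), i_pa=np.concatenate(i_all),
                        v_mv=np.concatenate(v_all), episodes=episodes,
                        capacitance_pf=capacitance_pf)


@dataclass
class RatioSensorData:
    """Two-channel ratiometric-sensor movie with its generative truth."""

    i_fret: np.ndarray       # (T, H, W)
    i_cerulean: np.ndarray   # (T, H, W)
    timestamps: np.ndarray
    cell_labels: np.ndarray
    true_ratio: np.ndarray   # (T,) common to all cells (spatially uniform)
    background_level: float


def simulate_ratio_sensor(protocol: ConditionProtocol, ratio_targets: dict,
                          shape=DEFAULT_SHAPE, timestamps=None, n_cells: int = 3,
                          tau_s: float = 30.0, seed: int = 0,
                          noise: NoiseModel | None = None,
                          expression_mean: float = DEFAULT_EXPRESSION_MEAN) -> RatioSensorData:
    """Ratiometric (ionic-strength-style) sensor movie.

    The FRET/Cerulean ratio relaxes first-order toward the current
    condition's target, uniformly across each cell (the sensor change is
    spatially homogeneous by construction); noise as in the three-cube
    renderer.  ``ratio_targets`` maps condition labels to target ratios
    (baseline condition should map to 1.0 times the basal ratio).
    """
    if any(v <= 0 for v in ratio_targets.values()):
        raise ValidationError("ratio targets must be positive")
    if timestamps is None:
        timestamps = np.arange(protocol.start_s, protocol.end_s + 1e-9, 10.0)
    timestamps = np.asarray(timestamps, dtype=float)
    noise = noise or NoiseModel()
    rng = np.random.default_rng(seed + 3)
    labels, c_map, *_ = make_cell_field(n_cells, shape, seed,
                                        expression_mean=expression_mean)
    # relax the ratio toward per-segment targets, exact piecewise exponential
    ratio = np.empty(len(timestamps))
    r = ratio_targets[protocol.segments[0].condition]
    t_prev = protocol.start_s
    ti = 0
    for seg in protocol.segments:
        tgt = ratio_targets[seg.condition]
        while ti < len(timestamps) and timestamps[ti] <= seg.end_s + 1e-9:
            t = timestamps[ti]
            if t < seg.start_s - 1e-9:
                ti += 1
                continue
            r = tgt + (r - tgt) * np.exp(-(t - t_prev) / tau_s)
            ratio[ti] = r
            t_prev = t
            ti += 1
        r = tgt + (r - tgt) * np.exp(-(seg.end_s - t_prev) / tau_s)
        t_prev = seg.end_s
    bg = noise.background_level
    i_fret, i_cer = [], []
    for t in range(len(timestamps)):
        cer_sig = c_map
        fret_sig = ratio[t] * c_map
        frames = []
        for sig in (fret_sig, cer_sig):
            img = sig + bg
            if noise.poisson_enabled:
                img = rng.poisson(img).astype(float)
            if noise.read_sd > 0:
                img = img + noise.read_sd * rng.standard_normal(img.shape)
            frames.append(np.clip(img, 0.0, SATURATION))
        i_fret.append(frames[0])
        i_cer.append(frames[1])
    return RatioSensorData(i_fret=np.stack(i_fret), i_cerulean=np.stack(i_cer),
                           timestamps=timestamps, cell_labels=labels,
                           true_ratio=ratio, background_level=bg)


def truth_sidecar(truth: GroundTruth, timestamps) -> pd.DataFrame:
    """Tidy per-cell per-time-point ground-truth table (the CSV sidecar)."""
    analytic = truth.analytic_cfret()
    rows = []
    for c in range(truth.n_cells):
        for ti, t in enumerate(timestamps):
            rows.append({"cell_id": c + 1, "t_s": float(t),
                         "true_efficiency": float(truth.efficiency[ti, c]),
                         "analytic_cfret": float(analytic[ti, c])})
    return pd.DataFrame(rows)
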