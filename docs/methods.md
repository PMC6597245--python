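# Methods

## The measurement model

Three-cube sensitized-emission FRET acquires three wide-field images per
time point: donor excitation/donor emission (I_DD), donor
excitation/acceptor emission (I_DA, the FRET channel) and acceptor
excitation/acceptor emission (I_AA). The FRET channel mixes three
contributions: true sensitized emission, donor emission bleeding through the
acceptor emission filter (fraction β of I_DD), and acceptor fluorescence
from direct excitation by the donor-excitation light (fraction γ of I_AA).
The corrected FRET index removes the two crosstalk terms and normalizes by
acceptor abundance:

    cFRET = (I_DA − β·I_DD − γ·I_AA) / I_AA

cFRET is a relative index, not an absolute FRET efficiency — converting to
efficiency would require the instrument G-factor, which the three-cube
protocol does not determine. All downstream comparisons therefore use
per-cell *normalized* cFRET (percent of each cell's mean during the initial
baseline condition), which cancels the unknown proportionality.

## Processing chain

Per channel and time point: background subtraction, Gaussian blur, validity
masking, then the cFRET quotient on valid pixels.

- **Background** is either a constant offset (default; the synthetic data
  has a known constant background) or a rolling-ball subtraction — the
  grayscale morphological opening with a ball-shaped (hemisphere-height)
  structuring element, radius 50 px by default, paraboloid variant behind a
  flag. Constant-offset subtraction is deliberately *not* clipped at zero:
  clipping rectifies zero-mean background noise into a positive offset
  (mean ≈ 0.8·σ for Poisson-like noise), which would defeat
  sd-based thresholding and bias ratio estimators.
- **Blur** σ = 2 px, applied after subtraction and before the quotient
  (the PixFRET order).
- **Validity**: a pixel is quantified iff, in every channel, the processed
  intensity exceeds `threshold × background-noise sd` (threshold 1 — the
  PixFRET convention of a multiplier on noise sd, since only "threshold 1"
  is stated) and the raw intensity is below `saturation_margin ×
  saturation_level`. The noise sd is the scaled median absolute deviation
  of known background pixels when a background mask is available (synthetic
  data), otherwise of the rolling-ball residual's below-median pixels.
- **Unsharp mask** (σ = 3, weight 0.7) exists for display only and is
  logged as such; it never feeds quantification.

ROI reduction takes the mean (or median) over ROI ∩ valid pixels per time
point, reporting n_valid; empty intersections propagate NaN, never zero.
Polygon ROIs use pixel-center vertex coordinates with boundary pixels
included, so a (0,0)–(4,4) rectangle covers exactly 25 pixels — an
unambiguous, countable convention.

## Calibration of β and γ

Estimated from donor-only (β: I_DA vs I_DD) and acceptor-only (γ: I_DA vs
I_AA) samples, per field of view, pooled as the mean ± sd over FOVs with
day-level bookkeeping (default design 3 days × 3 FOVs). Two estimators:

- `ratio_mean` — mean per-pixel ratio (PixFRET parity);
- `regression_slope` (default) — least-squares slope through the origin
  with inverse-variance (shot noise) weights, algebraically the ratio of
  summed intensities Σ I_DA / Σ I_DD. The unweighted through-origin slope
  is attenuated by noise in the regressor (errors-in-variables; relative
  bias ≈ 1/mean counts), and the per-pixel ratio mean is biased upward by
  the same order; the weighted form is unbiased to O(1/total counts),
  which matters at the Monte-Carlo tolerances the test suite enforces.

Calibration masks on the *measured channel pair only* (denominator above a
3-sd background floor — the same convention as the ratio-map denominator
floor — plus saturation checks): a donor-only sample has no acceptor
signal, so a three-channel validity mask would reject every pixel. A purity
check warns when the unused channel's median exceeds 2 background sds;
it is evaluated on the unclipped raw channel to avoid rectification bias.
Both estimators are scale-invariant and agree exactly on noiseless
homogeneous data.

## The synthetic forward model

The generator is the test oracle: it emulates the swelling experiment with
known ground truth. Noiseless pixel model for a pixel with donor
concentration d, acceptor concentration a, efficiency E:

    I_DD = k_D·d·(1−E) + bg
    I_AA = k_A·a + bg
    I_DA = k_S·d·E + β·(I_DD−bg) + γ·(I_AA−bg) + bg

Sensitized emission is additive on top of the crosstalk terms — the minimal
model under which the correction equation is *exact*: after perfect
background subtraction, cFRET = k_S·d·E/(k_A·a) at every pixel. Optional
per-frame multiplicative bleaching (default off), then Poisson shot noise,
additive Gaussian read noise (sd 2), and clipping at the detector full
scale (65535) are applied in that order.

Cells are smooth blobs (radius ≈ 11 px with low-order Fourier boundary
perturbation) with *uniform within-cell* expression, log-normal across
cells (sd 0.5 on both fluorophores independently, so donor/acceptor ratios
vary between cells). Cells are separated by more than the blur support, so
smoothing never mixes two cells; combined with within-cell uniformity this
makes the analytic cFRET hold exactly even at blurred cell edges, which is
what lets the noiseless analysis-of-synthesis tests demand 1e−9 agreement.

**Kinetics.** The condition protocol (default: isotonic 340 mOsm for 70 s,
hypotonic 250 mOsm for 90 s, isotonic recovery 120 s; 10 s frame cadence)
drives a first-order relaxation of E toward a condition target: e_rest =
0.30 at baseline, e_rest + delta_e with delta_e = −0.03 under hypotonicity,
τ_on = 30 s on activation and τ_off = 45 s on recovery. First-order
relaxation is a modeling choice — the data constrain only that the change
completes within ~90 s — and the integration is exact piecewise-exponential
stepping, so closed-form checks hold to machine precision. Per-cell
variability multiplies e_rest and delta_e by independent 1 + N(0, 0.05)
factors. These defaults put the normalized cFRET drop measured by the
last-3-points window 90 s after the switch at ≈ 9%, inside the expected
5–10% band (the asymptotic drop is 10%; the window average sits slightly
below it).

**Other generators.** Calibration stacks zero one fluorophore (and hence
E). Acceptor bleaching multiplies the acceptor map by (1 − bleach_fraction)
inside the bleach region and scales E by (1 − bleach_fraction)·q, q = 1
meaning all donor quenching is attributable to surviving acceptors; the
donor dequench ratio after a full bleach is then exactly 1/(1−E). The
current generator couples conductance instantaneously to the activation
state, g = g_max·clip((E−e_rest)/delta_e, 0, 1), sampled during 0.5 s
episodes to −80 mV every 12 s (current in pA = conductance in nS × voltage
in mV, reversal at 0 mV). The ratiometric sensor relaxes a spatially
uniform FRET/Cerulean ratio toward per-condition targets.

What the generator does **not** emulate: optical blur/PSF, 3-D cell
geometry, structured background, organelle morphology, diffusion, or
acquisition photobleaching (off by default). Tests passing on this model
validate the *algebra and statistics* of the pipeline, not robustness to
those real-data effects.

## Statistics and conventions

- Two-tailed Student's t-test; classical pooled variance for unpaired
  comparisons (Welch behind a flag), paired for within-cell iso-vs-hypo
  windows (the same cells contribute both windows), unpaired for
  bleached-vs-control. Labels: `*` p ≤ 0.05, `**` p ≤ 0.005, `***`
  p ≤ 0.0005 (inclusive thresholds). Degenerate zero-variance samples with
  equal means return t = 0, p = 1.
- Aggregation at cell level (mean ± sd over cells) or experiment level
  (per-experiment means first, then mean ± s.e.m. over experiments).
- Window conventions follow the figure-legend style: first 7 baseline
  points, last 3 (or 5) points of a condition; windows are config keys,
  not hard-coded.
- Baseline for normalization is the initial run of baseline-condition time
  points only (≥ 3 required), never later returns to baseline.
- Recovery percentage: 100·(recovered − activated)/(baseline − activated)
  on the normalized scale. This definition reproduces both wash-out
  worked examples from their reported window means (95.2 → 99.4 gives
  87.5%, i.e. > 80%; 89.6 → 93.6 gives 38.5%, i.e. < 40%), which is the
  evidence for it; it is affine-invariant in its three inputs.
- Exponential kinetics fits use y = offset + amplitude·exp(−(t−t0)/τ) with
  deterministic initialization (offset = last value, amplitude = first −
  last, τ = span/3) and up to five seeded jittered restarts; episode
  currents average the 50–90% window of each step to avoid capacitive
  transients.

## Numerical and design notes

- cFRET values are never clipped; negative noise excursions enter ROI means
  (clipping would bias them). Invalid pixels carry NaN.
- The rolling-ball element is a true non-flat hemisphere; its opening on an
  isolated impulse leaves a curvature residual of order the second-largest
  element height (≈ 0.06 for radius 8) — the brute-force oracle tests
  compare exactly against erosion-then-dilation with the same element.
- Golgi-style masking thresholds at the 98th intensity percentile with a
  20 px minimum component area; both are package defaults (no published
  values exist) and are logged.
- Group assignment in bleaching experiments: a cell is "bleached" at ≥ 80%
  overlap with the bleach region, "control" at ≤ 5%; straddling cells are
  excluded. The thresholds are package choices standing in for
  by-eye assignment from the field diaphragm.
- Ratio maps use a denominator floor (default 3× background sd) to prevent
  blow-up; within-cell homogeneity is reported as a coefficient of
  variation rather than a binary call, since no quantitative criterion is
  established for it.
- Problem sizes in the test suite and acceptance script (96–256 px fields,
  3–20 cells, 50–200 Monte-Carlo seeds) were chosen as the smallest designs
  whose Monte-Carlo standard errors are decisively below the tolerances
  being asserted.
- All randomness flows from a single integer seed per experiment; identical
  seeds give bit-identical stacks, traces and CSV outputs.

## Known limitations

- β and γ are modeled as intensity-independent constants, matching their
  single-number use in the correction equation; PixFRET's
  intensity-dependent variant is out of scope.
- Absolute FRET efficiency is not estimated from three-cube data (no
  G-factor), and the bleaching ΔCFP → efficiency identity is asserted only
  in the synthetic model, where bleach completeness is known.
- Multi-round bleach kinetics are not modeled; only pre/post endpoints are
  analyzed.
- No drift correction, flat-field correction or registration; the forward
  model generates perfectly registered stacks.
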