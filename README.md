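# cubefret

Quantitative analysis of **three-cube sensitized-emission FRET** microscopy,
built around the readout used to monitor conformational changes of
volume-regulated anion channels (VRACs): inter-subunit FRET between
fluorescent proteins fused to the C-termini of LRRC8 subunits falls by
5–10% within ~90 s when cells swell in hypotonic buffer, tracking channel
activation.

The package is organised as an analysis project: every computation lives in
the importable library under `src/cubefret/`, and the numbered scripts under
`analysis/` are thin narrative drivers that run the stages in order and
write tables under `results/`.

## What it computes

**Corrected FRET (cFRET).** From the three filter-cube channels — donor
excitation/donor emission *I*<sub>DD</sub>, donor excitation/acceptor
emission *I*<sub>DA</sub> (the FRET channel), and acceptor
excitation/acceptor emission *I*<sub>AA</sub> — the pixel-wise corrected
FRET index is

```
cFRET = (I_DA − β·I_DD − γ·I_AA) / I_AA
```

where **β** is the donor emission bleed-through into the FRET channel and
**γ** the direct excitation of the acceptor by donor-excitation light. Both
are calibrated from donor-only and acceptor-only samples (3 days × 3 fields
of view). Maps are computed on background-subtracted, Gaussian-blurred
(σ = 2 px) channels with PixFRET-style validity masking (signal above 1
background-noise s.d. in every channel, saturated pixels excluded), reduced
over whole-cell ROIs and normalized per cell to the mean cFRET in the
initial isotonic period (100 = baseline).

**The other assays.**

- *Acceptor photobleaching* — donor dequenching after destroying the
  acceptor; in the forward model a full bleach raises donor intensity by
  exactly 100·E/(1−E) percent.
- *Ratiometric sensor analysis* — FRET/Cerulean ratio maps, normalized
  time courses, line profiles and a within-cell coefficient of variation
  for spatial uniformity.
- *Patch-clamp fluorometry* — steady-state currents from episodic voltage
  protocols (0.5 s steps to −80 mV every 12 s), exponential kinetics fits,
  and FRET/current co-kinetics.
- *Statistics* — two-tailed Student's t-tests with the `*`/`**`/`***`
  convention (p ≤ 0.05 / 0.005 / 0.0005), cell- and experiment-level
  aggregation, and recovery percentages
  `100·(recovered − activated)/(baseline − activated)`.

**Synthetic forward model.** Because every stage must be testable against
known ground truth, `cubefret.synthetic` simulates complete experiments:
blob-shaped cells with log-normal expression, first-order efficiency
kinetics driven by a buffer protocol, exact spectral mixing with known
β/γ, Poisson shot noise, Gaussian read noise, background and saturation.
The noiseless pixel model is constructed so that the cFRET equation is
exact: `cFRET = k_S·d·E/(k_A·a)` at every background-free pixel.

## Worked example

```sh
python analysis/01_simulate_experiments.py
python analysis/02_calibrate_crosstalk.py
python analysis/03_cfret_timecourses.py
```

prints

```
wrote swelling experiment (3 cells, T=29) and 18 calibration FOVs to results/simulated
beta = 0.6000 +/- 0.0006 (true 0.6), gamma = 0.1500 +/- 0.0005 (true 0.15), 9 FOVs over 3 days
3 cells; iso 100.0 vs hypo 91.3 (drop 8.7%), paired t p = 3.46e-03 (**)
```

i.e. the crosstalk factors are recovered to three decimals from the noisy
single-label stacks, and the simulated hypotonic switch produces an 8.7%
drop in normalized cFRET (inside the expected 5–10% band), significant in a
paired comparison of the first seven isotonic against the last three
hypotonic time points. The remaining drivers
(`04_acceptor_bleach.py` … `07_group_statistics.py`) run the photobleach,
ratio-sensor, patch-fluorometry and group-statistics stages the same way.

A `cubefret` command-line interface exposes the same stages
(`cubefret simulate|calibrate|cfret|bleach|ratio|stats|pcf`); seeded runs
are byte-reproducible.

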