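#!/usr/bin/env python
"""Estimate the spectral correction factors beta and gamma.

Reads the simulated donor-only and acceptor-only stacks, estimates the donor
bleed-through (I_DA vs I_DD) and acceptor cross-excitation (I_DA vs I_AA)
per field of view, pools across the 3 x 3 day/FOV design, and writes
results/calibration.json.  With the default photon budget the estimates land
within a fraction of a percent of the generative truth (beta 0.60,
gamma 0.15).
"""

import json
from pathlib import Path

import numpy as np

from cubefret import calibration as cal
from cubefret import io_core
from cubefret.imageops import ProcessingParams

SIM = Path("results/simulated")


def load_group(prefix):
    stacks, masks, days = [], [], []
    for path in sorted(SIM.glob(f"{prefix}_day*_fov*.tiff")):
        stacks.append(io_core.read_three_cube_tiff(path))
        labels = np.loadtxt(path.with_name(path.stem + "_labels.txt"), dtype=int)
        masks.append(labels == 0)
        days.append(int(path.stem.split("day")[1].split("_")[0]))
    return stacks, masks, days


def main():
    truth = json.loads((SIM / "truth.json").read_text())
    bg = truth["background_level"]
    params = ProcessingParams()
    d_stacks, d_masks, days = load_group("donor_only")
    a_stacks, a_masks, _ = load_group("acceptor_only")
    b_fov, *_ = cal.estimate_beta(d_stacks, params, background_level=bg,
                                  background_masks=d_masks)
    g_fov, *_ = cal.estimate_gamma(a_stacks, params, background_level=bg,
                                   background_masks=a_masks)
    factors = cal.pool_calibration(b_fov, g_fov, days)
    out = {"beta": factors.beta, "gamma": factors.gamma,
           "beta_sd": factors.beta_sd, "gamma_sd": factors.gamma_sd,
           "n_fovs": factors.n_fovs, "n_days": factors.n_days,
           "method": factors.method}
    Path("results").mkdir(exist_ok=True)
    with open("results/calibration.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(f"beta = {factors.beta:.4f} +/- {factors.beta_sd:.4f} "
          f"(true {truth['beta_true']}), gamma = {factors.gamma:.4f} "
          f"+/- {factors.gamma_sd:.4f} (true {truth['gamma_true']}), "
          f"{factors.n_fovs} FOVs over {factors.n_days} days")


if __name__ == "__main__":
    main()
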