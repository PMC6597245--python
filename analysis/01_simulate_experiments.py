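#!/usr/bin/env python
"""Simulate the synthetic datasets every later analysis step consumes.

Generates one default swelling experiment (iso 340 mOsm -> hypo 250 mOsm ->
iso; 3 cells, 10 s cadence), the single-label calibration stacks (3 days x 3
FOVs of donor-only and acceptor-only cells), and writes the stacks as TIFF
plus ground-truth sidecars under results/simulated/.
"""

import json
import sys
from pathlib import Path

import numpy as np

from cubefret import io_core
from cubefret import synthetic as syn

OUT = Path("results/simulated")


def main(seed: int = 1):
    OUT.mkdir(parents=True, exist_ok=True)
    truth, protocol, ts = syn.default_ground_truth(seed=seed)
    stack = syn.render_three_cube(truth, ts)
    io_core.write_three_cube_tiff(OUT / "swelling_stack.tiff", stack)
    io_core.write_protocol_csv(OUT / "protocol.csv", protocol)
    syn.truth_sidecar(truth, ts).to_csv(OUT / "swelling_truth.csv", index=False)
    np.savetxt(OUT / "cell_labels.txt", truth.cell_labels, fmt="%d")
    with open(OUT / "truth.json", "w") as fh:
        json.dump({"beta_true": truth.beta_true, "gamma_true": truth.gamma_true,
                   "n_cells": truth.n_cells, "seed": seed,
                   "background_level": truth.noise.background_level}, fh, indent=1)

    donor, acceptor = syn.make_calibration_stacks(seed=seed + 1)
    for which, stacks in (("donor_only", donor), ("acceptor_only", acceptor)):
        for k, (day, s, t) in enumerate(stacks):
            io_core.write_three_cube_tiff(OUT / f"{which}_day{day}_fov{k % 3}.tiff", s)
            np.savetxt(OUT / f"{which}_day{day}_fov{k % 3}_labels.txt",
                       t.cell_labels, fmt="%d")
    print(f"wrote swelling experiment ({truth.n_cells} cells, "
          f"T={stack.n_timepoints}) and {len(donor) + len(acceptor)} "
          f"calibration FOVs to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
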