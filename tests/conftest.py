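import logging

import numpy as np
import pytest

from cubefret import calibration as cal
from cubefret import io_core, imageops
from cubefret import synthetic as syn

logging.disable(logging.WARNING)


def rois_from_labels(labels, extra=None):
    """Cell ROIs (one per nonzero label) plus optional extra ROIs."""
    rois = [io_core.Roi(roi_id=f"cell{i}", kind="cell", mask=labels == i)
            for i in range(1, labels.max() + 1)]
    if extra:
        rois += extra
    return io_core.RoiSet(rois=rois, image_shape=labels.shape)


@pytest.fixture(scope="session")
def noiseless():
    return syn.NoiseModel(poisson_enabled=False, read_sd=0.0, background_level=0.0)


@pytest.fixture(scope="session")
def noiseless_experiment(noiseless):
    """Noiseless, background-free default experiment: truth, protocol, times, stack."""
    truth, protocol, ts = syn.default_ground_truth(n_cells=3, seed=11,
                                                   noise=noiseless)
    stack = syn.render_three_cube(truth, ts)
    return truth, protocol, ts, stack


@pytest.fixture(scope="session")
def true_factors():
    return cal.CorrectionFactors(beta=syn.DEFAULT_BETA, gamma=syn.DEFAULT_GAMMA)


@pytest.fixture
def params():
    return imageops.ProcessingParams()
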