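import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubefret import calibration as cal
from cubefret import errors, io_core, sefret
from cubefret import synthetic as syn
from cubefret.imageops import ProcessingParams
from tests.conftest import rois_from_labels


class TestCfretPixel:
    def test_direct_substitution(self):
        f = cal.CorrectionFactors(beta=0.5, gamma=0.4)
        assert sefret.cfret_pixel(10.0, 0.0, 5.0, f) == pytest.approx(1.6)

    def test_algebraic_zero(self):
        f = cal.CorrectionFactors(beta=0.5, gamma=0.4)
        i_dd, i_aa = 30.0, 20.0
        i_da = 0.5 * i_dd + 0.4 * i_aa
        assert sefret.cfret_pixel(i_da, i_dd, i_aa, f) == pytest.approx(0.0, abs=1e-14)

    def test_thousand_random_tuples_vs_oracle(self):
        """Independently coded arithmetic agrees to 1e-12."""
        rng = np.random.default_rng(12)
        f = cal.CorrectionFactors(beta=0.6, gamma=0.15)
        for _ in range(1000):
            da, dd, aa = rng.uniform(0.1, 1000, 3)
            ours = sefret.cfret_pixel(da, dd, aa, f)
            oracle = da / aa - f.beta * (dd / aa) - f.gamma
            assert abs(ours - oracle) < 1e-12

    def test_nonpositive_denominator_is_nan(self):
        f = cal.CorrectionFactors(beta=0.6, gamma=0.15)
        assert np.isnan(sefret.cfret_pixel(10.0, 1.0, 0.0, f))
        assert np.isnan(sefret.cfret_pixel(10.0, 1.0, -5.0, f))

    @given(c=st.floats(0.01, 100.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_common_rescaling(self, c):
        f = cal.CorrectionFactors(beta=0.6, gamma=0.15)
        rng = np.random.default_rng(7)
        da, dd, aa = rng.uniform(1, 100, 3)
        assert sefret.cfret_pixel(c * da, c * dd, c * aa, f) == pytest.approx(
            sefret.cfret_pixel(da, dd, aa, f), rel=1e-9)


class TestCfretMap:
    def test_noiseless_map_equals_analytic(self, noiseless_experiment, true_factors,
                                           params):
        truth, _, _, stack = noiseless_experiment
        m = sefret.cfret_map(stack.frame(0), true_factors, params,
                             stack.saturation_level, background_level=0.0,
                             background_mask=truth.cell_labels == 0)
        analytic = truth.analytic_cfret()[0]
        for c in range(truth.n_cells):
            sel = (truth.cell_labels == c + 1) & m.valid
            assert sel.any()
            np.testing.assert_allclose(m.cfret[sel], analytic[c], rtol=1e-9)

    def test_zero_efficiency_map_is_zero(self, noiseless, true_factors, params):
        truth, _, ts = syn.default_ground_truth(n_cells=2, shape=(64, 64), seed=6,
                                                noise=noiseless, timestamps=[0.0])
        truth.efficiency[:] = 0.0
        stack = syn.render_three_cube(truth, ts)
        m = sefret.cfret_map(stack.frame(0), true_factors, params,
                             stack.saturation_level, background_level=0.0,
                             background_mask=truth.cell_labels == 0)
        assert np.nanmax(np.abs(m.cfret[m.valid])) < 1e-9

    def test_saturated_pixel_locally_invalidated(self, noiseless, true_factors):
        truth, _, ts = syn.default_ground_truth(n_cells=1, shape=(64, 64), seed=6,
                                                noise=noiseless, timestamps=[0.0])
        stack = syn.render_three_cube(truth, ts)
        cell_px = np.argwhere(truth.cell_labels == 1)
        i, j = cell_px[len(cell_px) // 2]
        stack.i_aa[0, i, j] = stack.saturation_level
        p = ProcessingParams(gaussian_sigma_px=0.0)
        m = sefret.cfret_map(stack.frame(0), true_factors, p,
                             stack.saturation_level, background_level=0.0,
                             background_mask=truth.cell_labels == 0)
        assert not m.valid[i, j]
        neighbors = [(i + 1, j), (i - 1, j), (i, j + 1), (i, j - 1)]
        assert all(m.valid[a, b] for a, b in neighbors)

    def test_invalid_pixels_are_nan_not_zero(self, noiseless_experiment,
                                             true_factors, params):
        truth, _, _, stack = noiseless_experiment
        m = sefret.cfret_map(stack.frame(0), true_factors, params,
                             stack.saturation_level, background_level=0.0,
                             background_mask=truth.cell_labels == 0)
        assert np.isnan(m.cfret[~m.valid]).all()


class TestRoiTimecourse:
    def test_noiseless_tracks_analytic(self, noiseless_experiment, true_factors,
                                       params):
        truth, protocol, ts, stack = noiseless_experiment
        rois = rois_from_labels(truth.cell_labels)
        tcs = sefret.roi_timecourse(stack, rois, true_factors, params, protocol,
                                    background_level=0.0,
                                    background_mask=truth.cell_labels == 0)
        analytic = truth.analytic_cfret()
        assert len(tcs) == truth.n_cells
        for c, tc in enumerate(tcs):
            np.testing.assert_allclose(tc.cfret_raw, analytic[:, c], rtol=1e-9)

    def test_expression_ratio_independence(self, noiseless, true_factors, params):
        """Cells with different donor/acceptor ratios but one efficiency
        time course have identical normalized traces."""
        truth, protocol, ts = syn.default_ground_truth(
            n_cells=2, shape=(96, 96), seed=13, noise=noiseless, cell_sd=0.0)
        # force very different expression ratios
        for i, scale in ((1, 1.0), (2, 4.0)):
            m = truth.cell_labels == i
            truth.donor_map[m] = 500.0 * scale
            truth.acceptor_map[m] = 900.0 / scale
        truth.donor_levels = np.array([500.0, 2000.0])
        truth.acceptor_levels = np.array([900.0, 225.0])
        stack = syn.render_three_cube(truth, ts)
        tcs = sefret.roi_timecourse(stack, rois_from_labels(truth.cell_labels),
                                    true_factors, params, protocol,
                                    background_level=0.0,
                                    background_mask=truth.cell_labels == 0)
        for tc in tcs:
            sefret.normalize_to_baseline(tc, "iso")
        np.testing.assert_allclose(tcs[0].cfret_norm, tcs[1].cfret_norm, rtol=1e-9)

    def test_empty_roiset_empty_output(self, noiseless_experiment, true_factors,
                                       params):
        truth, protocol, ts, stack = noiseless_experiment
        rois = io_core.RoiSet(rois=[], image_shape=truth.cell_labels.shape)
        assert sefret.roi_timecourse(stack, rois, true_factors, params,
                                     protocol) == []


def make_tc(values, conditions, t=None):
    values = np.asarray(values, dtype=float)
    return sefret.FretTimeCourse(
        cell_id="c", t_s=np.asarray(t if t is not None
                                    else np.arange(len(values)) * 10.0),
        cfret_raw=values, n_valid=np.full(len(values), 10),
        condition=list(conditions))


class TestNormalize:
    def test_flat_trace_normalizes_to_100(self):
        tc = make_tc([0.3] * 6, ["iso"] * 3 + ["hypo"] * 3)
        sefret.normalize_to_baseline(tc, "iso")
        np.testing.assert_allclose(tc.cfret_norm, 100.0)

    def test_arithmetic_example(self):
        tc = make_tc([0.30, 0.30, 0.30, 0.276], ["iso"] * 3 + ["hypo"])
        sefret.normalize_to_baseline(tc, "iso")
        assert tc.cfret_norm[-1] == pytest.approx(92.0)

    def test_baseline_excludes_later_isotonic_returns(self):
        """Only the initial isotonic run defines the baseline."""
        tc = make_tc([0.3, 0.3, 0.3, 0.2, 0.6, 0.6],
                     ["iso", "iso", "iso", "hypo", "iso", "iso"])
        sefret.normalize_to_baseline(tc, "iso")
        assert tc.baseline_mean == pytest.approx(0.3)

    def test_short_baseline_rejected(self):
        tc = make_tc([0.3, 0.3, 0.2], ["iso", "iso", "hypo"])
        with pytest.raises(errors.NormalizationError):
            sefret.normalize_to_baseline(tc, "iso")


class TestConditionWindow:
    def test_constant_trace_any_window(self):
        tc = make_tc([0.3] * 10, ["iso"] * 5 + ["hypo"] * 5)
        sefret.normalize_to_baseline(tc, "iso")
        assert sefret.condition_window_mean(tc, "hypo", "last_k", 3) == pytest.approx(100.0)

    def test_last_three_arithmetic(self):
        tc = make_tc([0.3] * 7 + [0.28, 0.27, 0.26], ["iso"] * 7 + ["hypo"] * 3)
        sefret.normalize_to_baseline(tc, "iso")
        expected = 100.0 * np.mean([0.28, 0.27, 0.26]) / 0.3
        assert sefret.condition_window_mean(tc, "hypo", "last_k", 3) == pytest.approx(expected)

    def test_first_seven_iso_is_own_baseline(self):
        rng = np.random.default_rng(0)
        vals = np.concatenate([0.3 + 0.01 * rng.standard_normal(7),
                               0.27 + 0.01 * rng.standard_normal(3)])
        tc = make_tc(vals, ["iso"] * 7 + ["hypo"] * 3)
        sefret.normalize_to_baseline(tc, "iso")
        assert sefret.condition_window_mean(tc, "iso", "first_k", 7) == pytest.approx(100.0)

    def test_absent_condition_rejected(self):
        tc = make_tc([0.3] * 6, ["iso"] * 6)
        sefret.normalize_to_baseline(tc, "iso")
        with pytest.raises(errors.WindowError):
            sefret.condition_window_mean(tc, "hypo", "last_k", 3)


def test_monotone_drop_in_delta_e(noiseless, true_factors, params):
    """A larger programmed |delta_e| strictly deepens the measured drop."""
    drops = []
    for delta in (-0.01, -0.02, -0.03, -0.04, -0.05):
        kin = syn.ActivationKinetics(delta_e=delta)
        truth, protocol, ts = syn.default_ground_truth(
            n_cells=1, shape=(64, 64), seed=21, noise=noiseless, kinetics=kin,
            cell_sd=0.0)
        stack = syn.render_three_cube(truth, ts)
        tcs = sefret.roi_timecourse(stack, rois_from_labels(truth.cell_labels),
                                    true_factors, params, protocol,
                                    background_level=0.0,
                                    background_mask=truth.cell_labels == 0)
        sefret.normalize_to_baseline(tcs[0], "iso")
        drops.append(100.0 - sefret.condition_window_mean(tcs[0], "hypo", "last_k", 3))
    assert np.all(np.diff(drops) > 0)
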