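import numpy as np
import pytest

from cubefret import errors, io_core
from cubefret import synthetic as syn


class TestCellField:
    def test_zero_cells_rejected(self):
        with pytest.raises(errors.ParameterError):
            syn.make_cell_field(0)

    def test_three_distinct_labels(self):
        labels, *_ = syn.make_cell_field(3, (128, 128), seed=7)
        assert set(np.unique(labels)) == {0, 1, 2, 3}

    def test_expression_positive_exactly_on_cells(self):
        labels, donor, acceptor, *_ = syn.make_cell_field(3, (128, 128), seed=7)
        assert np.all((donor > 0) == (labels > 0))
        assert np.all((acceptor > 0) == (labels > 0))

    def test_impossible_placement_raises(self):
        with pytest.raises(errors.PlacementError):
            syn.make_cell_field(20, (48, 48), seed=0)


class TestEfficiency:
    def test_constant_iso_protocol_stays_at_rest(self):
        protocol = io_core.ConditionProtocol(segments=[
            io_core.ProtocolSegment(0, 300, "iso", 340)])
        kin = syn.ActivationKinetics()
        eff = syn.simulate_efficiency(protocol, kin, np.arange(0, 301, 10.0), 2,
                                      cell_sd=0.0, seed=0)
        np.testing.assert_allclose(eff, kin.e_rest, rtol=1e-12)

    def test_step_response_matches_closed_form(self):
        """After a switch at t=0 with tau=30 s, E(90) follows the exact exponential."""
        protocol = io_core.ConditionProtocol(segments=[
            io_core.ProtocolSegment(-1e-6, 0, "iso", 340),
            io_core.ProtocolSegment(0, 300, "hypo", 250)])
        kin = syn.ActivationKinetics(tau_on_s=30.0)
        ts = np.arange(0.0, 301, 10.0)
        eff = syn.simulate_efficiency(protocol, kin, ts, 1, cell_sd=0.0, seed=0)
        target = kin.e_rest + kin.delta_e
        expected = target + (kin.e_rest - target) * np.exp(-90.0 / 30.0)
        assert eff[list(ts).index(90.0), 0] == pytest.approx(expected, rel=1e-12)

    def test_zero_delta_invariant_under_switches(self):
        protocol = io_core.default_protocol()
        kin = syn.ActivationKinetics(delta_e=0.0)
        eff = syn.simulate_efficiency(protocol, kin, np.arange(0, 281, 10.0), 3,
                                      cell_sd=0.0, seed=0)
        assert np.ptp(eff) == 0

    def test_timestamp_outside_protocol_raises(self):
        protocol = io_core.default_protocol()
        with pytest.raises(errors.ValidationError):
            syn.simulate_efficiency(protocol, syn.ActivationKinetics(),
                                    [0.0, protocol.end_s + 50], 1)


def single_cell_truth(e, d=100.0, a=100.0, noise=None, shape=(48, 48)):
    labels = np.zeros(shape, dtype=int)
    labels[16:32, 16:32] = 1
    noise = noise or syn.NoiseModel(poisson_enabled=False, read_sd=0.0,
                                    background_level=0.0)
    return syn.GroundTruth(
        donor_map=np.where(labels > 0, d, 0.0), acceptor_map=np.where(labels > 0, a, 0.0),
        efficiency=np.array([[e]]), beta_true=0.6, gamma_true=0.15,
        brightness=syn.Brightness(), noise=noise, cell_labels=labels,
        donor_levels=np.array([d]), acceptor_levels=np.array([a]), seed=0)


class TestRender:
    def test_zero_efficiency_gives_pure_crosstalk(self):
        truth = single_cell_truth(e=0.0)
        stack = syn.render_three_cube(truth, [0.0])
        expected = 0.6 * stack.i_dd[0] + 0.15 * stack.i_aa[0]
        np.testing.assert_allclose(stack.i_da[0], expected, atol=1e-12)

    def test_analytic_cfret_on_uniform_cell(self):
        truth = single_cell_truth(e=0.2, d=100.0, a=100.0)
        stack = syn.render_three_cube(truth, [0.0])
        cell = truth.cell_labels > 0
        cfret = (stack.i_da[0][cell] - 0.6 * stack.i_dd[0][cell]
                 - 0.15 * stack.i_aa[0][cell]) / stack.i_aa[0][cell]
        np.testing.assert_allclose(cfret, 0.2, rtol=1e-12)

    def test_poisson_mean_matches_analytic(self):
        """Shot-noise corrected FRET is unbiased over >= 1e4 cell pixels."""
        noise = syn.NoiseModel(poisson_enabled=True, read_sd=0.0, background_level=0.0)
        labels = np.ones((128, 128), dtype=int)
        truth = syn.GroundTruth(
            donor_map=np.full((128, 128), 2000.0),
            acceptor_map=np.full((128, 128), 2000.0),
            efficiency=np.array([[0.2]]), beta_true=0.6, gamma_true=0.15,
            brightness=syn.Brightness(), noise=noise, cell_labels=labels,
            donor_levels=np.array([2000.0]), acceptor_levels=np.array([2000.0]), seed=3)
        stack = syn.render_three_cube(truth, [0.0])
        cfret = (stack.i_da[0] - 0.6 * stack.i_dd[0] - 0.15 * stack.i_aa[0]) / stack.i_aa[0]
        se = cfret.std() / np.sqrt(cfret.size)
        assert abs(cfret.mean() - 0.2) < 2 * se + 1e-4

    def test_efficiency_out_of_range_rejected(self):
        with pytest.raises(errors.ValidationError):
            single_cell_truth(e=1.0)

    def test_seeded_determinism(self):
        noise = syn.NoiseModel()
        t1 = single_cell_truth(0.2, noise=noise)
        t2 = single_cell_truth(0.2, noise=noise)
        s1 = syn.render_three_cube(t1, [0.0])
        s2 = syn.render_three_cube(t2, [0.0])
        np.testing.assert_array_equal(s1.i_da, s2.i_da)


class TestCalibrationStacks:
    def test_donor_only_ratio_is_beta(self, noiseless):
        donor, _ = syn.make_calibration_stacks(n_days=1, n_fovs_per_day=1, seed=1,
                                               noise=noiseless)
        _, stack, truth = donor[0]
        cell = truth.cell_labels > 0
        np.testing.assert_allclose(stack.i_da[0][cell] / stack.i_dd[0][cell],
                                   truth.beta_true, rtol=1e-12)

    def test_acceptor_only_ratio_is_gamma(self, noiseless):
        _, acceptor = syn.make_calibration_stacks(n_days=1, n_fovs_per_day=1, seed=1,
                                                  noise=noiseless)
        _, stack, truth = acceptor[0]
        cell = truth.cell_labels > 0
        np.testing.assert_allclose(stack.i_da[0][cell] / stack.i_aa[0][cell],
                                   truth.gamma_true, rtol=1e-12)

    def test_three_days_three_fovs_yields_nine_stacks(self, noiseless):
        donor, acceptor = syn.make_calibration_stacks(n_days=3, n_fovs_per_day=3,
                                                      seed=0, noise=noiseless)
        assert len(donor) == 9 and len(acceptor) == 9
        assert sorted({d for d, _, _ in donor}) == [0, 1, 2]


class TestBleachSimulation:
    def test_full_bleach_donor_dequench_ratio(self, noiseless):
        truth = single_cell_truth(e=0.2)
        region = np.ones_like(truth.cell_labels, dtype=bool)
        pre, post = syn.simulate_bleach_experiment(truth, region, 1.0)
        cell = truth.cell_labels > 0
        np.testing.assert_allclose(post.i_dd[0][cell] / pre.i_dd[0][cell],
                                   1.0 / (1.0 - 0.2), rtol=1e-12)

    def test_zero_fraction_is_identity(self):
        truth = single_cell_truth(e=0.2)
        region = np.ones_like(truth.cell_labels, dtype=bool)
        pre, post = syn.simulate_bleach_experiment(truth, region, 0.0)
        np.testing.assert_array_equal(pre.i_dd, post.i_dd)
        np.testing.assert_array_equal(pre.i_aa, post.i_aa)

    def test_outside_region_unchanged(self):
        truth = single_cell_truth(e=0.2)
        region = np.zeros_like(truth.cell_labels, dtype=bool)
        region[:8, :8] = True  # away from the cell
        pre, post = syn.simulate_bleach_experiment(truth, region, 1.0)
        cell = truth.cell_labels > 0
        np.testing.assert_array_equal(pre.i_dd[0][cell], post.i_dd[0][cell])

    def test_invalid_fraction_rejected(self):
        truth = single_cell_truth(e=0.2)
        with pytest.raises(errors.ValidationError):
            syn.simulate_bleach_experiment(truth, truth.cell_labels > 0, 1.5)


class TestCurrentTrace:
    def test_resting_efficiency_gives_zero_current(self):
        kin = syn.ActivationKinetics()
        ts = np.arange(0.0, 121, 10.0)
        eff = np.full(len(ts), kin.e_rest)
        trace = syn.simulate_current_trace(ts, eff, kin, g_max_ns=10.0)
        assert np.all(trace.i_pa == 0)

    def test_full_activation_plateau(self):
        kin = syn.ActivationKinetics()
        ts = np.arange(0.0, 121, 10.0)
        eff = np.full(len(ts), kin.e_rest + kin.delta_e)
        trace = syn.simulate_current_trace(ts, eff, kin, g_max_ns=10.0)
        np.testing.assert_allclose(trace.i_pa, -80.0 * 10.0, rtol=1e-12)

    def test_degenerate_coupling_rejected(self):
        kin = syn.ActivationKinetics(delta_e=0.0)
        with pytest.raises(errors.ParameterError):
            syn.simulate_current_trace([0, 10], [0.3, 0.3], kin, g_max_ns=10.0)

    def test_episode_table_structure(self):
        kin = syn.ActivationKinetics()
        ts = np.arange(0.0, 121, 10.0)
        trace = syn.simulate_current_trace(ts, np.full(len(ts), kin.e_rest), kin)
        assert set(trace.episodes.columns) >= {"episode_index", "t_start_s",
                                               "v_step_mv", "duration_s"}
        assert np.allclose(np.diff(trace.episodes["t_start_s"]), 12.0)


class TestRatioSensor:
    def test_constant_protocol_flat_ratio(self, noiseless):
        protocol = io_core.ConditionProtocol(segments=[
            io_core.ProtocolSegment(0, 200, "iso", 340)])
        data = syn.simulate_ratio_sensor(protocol, {"iso": 1.0}, shape=(64, 64),
                                         n_cells=1, seed=2, noise=noiseless)
        cell = data.cell_labels > 0
        ratios = data.i_fret[:, cell] / data.i_cerulean[:, cell]
        np.testing.assert_allclose(ratios, 1.0, rtol=1e-12)

    def test_hypo_target_spatially_uniform(self, noiseless):
        protocol = io_core.default_protocol()
        data = syn.simulate_ratio_sensor(protocol, {"iso": 1.0, "hypo": 1.05},
                                         shape=(64, 64), n_cells=1, seed=2,
                                         noise=noiseless)
        cell = data.cell_labels > 0
        t_last_hypo = np.max(np.where(data.timestamps < 160.0))
        rmap = data.i_fret[t_last_hypo][cell] / data.i_cerulean[t_last_hypo][cell]
        assert np.ptp(rmap) < 1e-12  # uniform within the cell
        assert rmap[0] == pytest.approx(data.true_ratio[t_last_hypo], rel=1e-12)

    def test_nonpositive_target_rejected(self):
        with pytest.raises(errors.ValidationError):
            syn.simulate_ratio_sensor(io_core.default_protocol(),
                                      {"iso": 1.0, "hypo": -0.5})


def test_single_seed_controls_everything():
    """Identical seeds give bit-identical noisy experiments end to end."""
    a = syn.default_ground_truth(n_cells=2, shape=(64, 64), seed=9)
    b = syn.default_ground_truth(n_cells=2, shape=(64, 64), seed=9)
    np.testing.assert_array_equal(a[0].efficiency, b[0].efficiency)
    sa = syn.render_three_cube(a[0], a[2])
    sb = syn.render_three_cube(b[0], b[2])
    np.testing.assert_array_equal(sa.i_da, sb.i_da)
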