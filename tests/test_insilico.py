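import numpy as np
import pytest

from sedcm.cmc import predict_spectrum
from sedcm.insilico import (
    detect_transition,
    find_escape_parameters,
    fit_group_mean,
    parameter_grid_spectra,
    probe_power,
    sensitivity_screen,
    trajectory_power,
)
from sedcm.spectra import SpectralData

from conftest import make_noisy


class TestGroupMean:
    def test_identical_spectra_equal_single_inversion(self, params, prior, default_spectrum):
        from sedcm.inversion import invert_spectrum

        single = invert_spectrum(default_spectrum, prior)
        group = fit_group_mean([default_spectrum] * 4, prior)
        np.testing.assert_allclose(group.posterior.mean, single.posterior.mean, atol=1e-10)

    def test_mean_spectrum_is_elementwise_mean(self, params):
        specs = [make_noisy(predict_spectrum(params), 0.2, s) for s in range(3)]
        mean = np.mean([s.values for s in specs], axis=0)
        stacked = np.mean(np.stack([s.values for s in specs]), axis=0)
        np.testing.assert_allclose(mean, stacked, atol=1e-12)

    def test_mismatched_grids_rejected(self, default_spectrum):
        other = SpectralData(default_spectrum.freqs[:-1], default_spectrum.values[:-1])
        with pytest.raises(ValueError, match="common frequency grid"):
            fit_group_mean([default_spectrum, other])


class TestParameterGrid:
    def test_zero_width_range_reproduces_base_spectrum(self, params, default_spectrum):
        grid = parameter_grid_spectra(params, ["g_ii_ss"], [(0.0, 0.0)], 3)
        for spec in grid.spectra:
            np.testing.assert_allclose(spec.values, default_spectrum.values, rtol=1e-10)

    def test_two_axes_evaluate_steps_squared_points(self, params):
        grid = parameter_grid_spectra(params, ["g_ii_ss", "g_ii_dp"],
                                      [(-0.2, 0.2), (-0.2, 0.2)], 5)
        assert grid.spectra.shape == (5, 5)
        assert grid.n_unstable + sum(s is not None for s in grid.spectra.ravel()) == 25

    def test_each_point_matches_direct_prediction(self, params):
        grid = parameter_grid_spectra(params, ["g_ii_ss"], [(-0.4, 0.4)], 5)
        offsets = grid.axes[0][1]
        for off, spec in zip(offsets, grid.spectra):
            direct = predict_spectrum(params.update({"g_ii_ss": off}))
            np.testing.assert_allclose(spec.values, direct.values, rtol=1e-12)

    def test_unknown_parameter_rejected(self, params):
        with pytest.raises(ValueError, match="unknown variable parameter"):
            parameter_grid_spectra(params, ["g_bogus"], [(-1, 1)], 3)

    def test_nonneuronal_axis_rejected(self, params):
        with pytest.raises(ValueError, match="unknown variable parameter"):
            parameter_grid_spectra(params, ["obs_gain"], [(-1, 1)], 3)


class TestTrajectory:
    def test_probe_defaults_to_25_hz(self, params):
        grid = parameter_grid_spectra(params, ["g_ii_ss", "g_ii_dp"],
                                      [(-0.1, 0.1), (-0.1, 0.1)], 3)
        rep = trajectory_power(grid)
        assert rep.probe_freq == 25.0

    def test_constant_grid_gives_constant_track(self, params):
        grid = parameter_grid_spectra(params, ["g_ii_ss", "g_ii_dp"],
                                      [(0.0, 0.0), (0.0, 0.0)], 4)
        rep = trajectory_power(grid)
        assert len(rep.power_track) == 4
        assert np.ptp(rep.power_track) < 1e-10 * rep.power_track[0]
        assert not rep.transition_detected

    def test_diagonal_has_n_entries(self, params):
        grid = parameter_grid_spectra(params, ["g_ii_ss", "g_ii_dp"],
                                      [(-0.2, 0.2), (-0.2, 0.2)], 7)
        assert len(trajectory_power(grid).power_track) == 7

    def test_non_square_grid_rejected(self, params):
        grid = parameter_grid_spectra(params, ["g_ii_ss", "g_ii_dp"],
                                      [(-0.2, 0.2), (-0.2, 0.2)], (3, 4))
        with pytest.raises(ValueError, match="square"):
            trajectory_power(grid)


class TestDetectTransition:
    def test_constant_track_has_no_transition(self):
        assert detect_transition(np.ones(10)) is None

    def test_constructed_step_detected_after_jump(self):
        track = np.array([1.0, 1.0, 1.0, 10.0, 10.0])
        assert detect_transition(track, np.log(3.0)) == 3

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            track = np.exp(rng.normal(0, 1, 12))
            low = detect_transition(track, 0.5)
            high = detect_transition(track, 2.0)
            if high is not None:
                assert low is not None  # raising the threshold never creates one

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            detect_transition(np.array([1.0, 0.0, 2.0]))

    def test_gaps_skipped_when_allowed(self):
        track = np.array([1.0, np.nan, 10.0, 10.0])
        assert detect_transition(track, np.log(3.0), allow_gaps=True) is None
        with pytest.raises(ValueError, match="gaps"):
            detect_transition(track, np.log(3.0))


class TestSensitivityScreen:
    def test_screen_covers_all_14_parameters(self, params):
        screen = sensitivity_screen(params, range_logunits=0.2, steps=3)
        assert len(screen) == 14
        assert set(screen) == set(params.variable_names)

    def test_zero_range_gives_constant_curves(self, params):
        screen = sensitivity_screen(params, range_logunits=0.0, steps=3)
        for d in screen.values():
            assert np.ptp(d["power"]) < 1e-10 * np.abs(d["power"]).max()

    def test_small_perturbation_slope_matches_finite_difference(self, params):
        screen = sensitivity_screen(params, range_logunits=0.02, steps=3)
        for name in ("g_ii_ss", "tau_ii"):
            offs = screen[name]["offsets"]
            pw = screen[name]["power"]
            slope = (pw[-1] - pw[0]) / (offs[-1] - offs[0])
            eps = 1e-4
            fd = (probe_power(params.update({name: eps}))
                  - probe_power(params.update({name: -eps}))) / (2 * eps)
            assert slope == pytest.approx(fd, rel=0.05)


class TestEscape:
    def test_identity_target_has_no_reductions(self, params, default_spectrum):
        df = find_escape_parameters(params, default_spectrum, range_logunits=0.5, steps=9)
        assert np.all(np.abs(df.distance_reduction) < 1e-9)
        assert not df.escape_route.any()

    def test_planted_tau_ss_target_ranks_first(self, params):
        target = predict_spectrum(params.update({"tau_ss": -0.8}))
        df = find_escape_parameters(params, target, range_logunits=1.0, steps=21)
        assert df.parameter.iloc[0] == "tau_ss"
        assert df.best_offset.iloc[0] == pytest.approx(-0.8, abs=0.1)

    def test_ranking_invariant_to_target_rescaling(self, params):
        target = predict_spectrum(params.update({"tau_ss": -0.6}))
        df1 = find_escape_parameters(params, target, range_logunits=1.0, steps=11)
        scaled = SpectralData(target.freqs, target.values * 7.3)
        df2 = find_escape_parameters(params, scaled, range_logunits=1.0, steps=11)
        assert list(df1.parameter) == list(df2.parameter)
        np.testing.assert_allclose(df1.distance, df2.distance, atol=1e-9)
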