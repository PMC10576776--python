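"""Kymograph construction, front-profile extraction, smoothing, wave
detection, normalization and group comparison."""

import numpy as np
import pandas as pd
import pytest

from helpers import profile_from_fn

from somiteclock import kymo as km
from somiteclock.synthetic import KymoSynthParams, synthesize_kymograph


def _extract_amplitudes(kymo, window_frames, n_waves):
    traj = km.locate_front(kymo, kymo.n_px, 0.5)
    raw = km.extract_front_profile(kymo, traj, 4)
    prof = km.smooth_resample(raw, 9, 2, 10)
    return km.detect_waves(prof, window_frames, n_waves, kymo.seven_somite_frame)


class TestBuildKymograph:
    def test_constant_stack_constant_kymograph(self):
        stack = np.full((4, 30, 50), 7.0)
        loi = [(15, 2), (15, 47)]
        kymo = km.build_kymograph(stack, loi, width_px=5)
        assert np.allclose(kymo.data, 7.0)

    def test_width_one_single_row_is_pixel_lookup(self):
        stack = np.arange(20, dtype=float).reshape(1, 1, 20)
        kymo = km.build_kymograph(stack, [(0, 0), (0, 19)], width_px=1)
        assert np.allclose(kymo.data[0], np.arange(20.0))

    def test_round_trip_from_known_kymograph(self):
        """A stack rendered from a known kymograph along a horizontal LOI is
        recovered within 1%."""
        rng = np.random.default_rng(8)
        truth = 100 + 10 * rng.random((6, 40))
        stack = np.repeat(truth[:, None, :], 31, axis=1)  # constant across rows
        kymo = km.build_kymograph(stack, [(15, 0), (15, 39)], width_px=15)
        assert np.allclose(kymo.data, truth, rtol=0.01)

    def test_loi_outside_image_rejected(self):
        stack = np.zeros((2, 10, 10))
        with pytest.raises(ValueError, match="exits"):
            km.build_kymograph(stack, [(5, 0), (5, 30)])


class TestLocateFront:
    def test_constant_extent_midpoint(self):
        kymo = km.Kymograph(np.zeros((5, 220)), 5.0, 2.6, 0)
        traj = km.locate_front(kymo, 200.0, 0.5)
        assert np.allclose(traj, 100.0)

    def test_small_fraction_pins_to_posterior(self):
        kymo = km.Kymograph(np.zeros((5, 220)), 5.0, 2.6, 0)
        traj = km.locate_front(kymo, 200.0, 1e-6)
        assert np.allclose(traj, 0.0, atol=1e-3)

    def test_shrinking_psm_linear_trajectory(self):
        kymo = km.Kymograph(np.zeros((11, 220)), 5.0, 2.6, 0)
        extent = np.linspace(200.0, 100.0, 11)
        traj = km.locate_front(kymo, extent, 0.6)
        assert np.allclose(traj, np.linspace(120.0, 60.0, 11))

    @pytest.mark.parametrize("f", [0.0, 1.0, -0.2, 1.5])
    def test_fraction_out_of_range_rejected(self, f):
        kymo = km.Kymograph(np.zeros((5, 220)), 5.0, 2.6, 0)
        with pytest.raises(ValueError):
            km.locate_front(kymo, 200.0, f)


class TestExtractFrontProfile:
    def test_constant_kymograph_constant_series(self):
        kymo = km.Kymograph(np.full((6, 50), 3.5), 5.0, 2.6, 0)
        out = km.extract_front_profile(kymo, np.full(6, 20.0), 4)
        assert np.allclose(out, 3.5)

    def test_width_one_is_column_readoff(self):
        data = np.tile(np.arange(50.0), (4, 1))
        kymo = km.Kymograph(data, 5.0, 2.6, 0)
        out = km.extract_front_profile(kymo, np.full(4, 13.0), 1)
        assert np.allclose(out, 13.0)

    def test_column_ramp_band_mean_by_enumeration(self):
        """I(x) = x, front 100.0, width 4: rounded center 100, band columns
        99..102, mean 100.5 (direct enumeration of the centering rule)."""
        data = np.tile(np.arange(200.0), (3, 1))
        kymo = km.Kymograph(data, 5.0, 2.6, 0)
        out = km.extract_front_profile(kymo, np.full(3, 100.0), 4)
        assert np.allclose(out, np.mean([99, 100, 101, 102]))

    def test_edge_band_clamped_with_warning(self):
        data = np.tile(np.arange(20.0), (3, 1))
        kymo = km.Kymograph(data, 5.0, 2.6, 0)
        with pytest.warns(UserWarning, match="clamp"):
            out = km.extract_front_profile(kymo, np.full(3, 0.0), 4)
        assert np.allclose(out, np.mean([0, 1, 2, 3]))


class TestSmoothResample:
    def test_linear_ramp_preserved(self):
        ramp = np.arange(50.0)
        prof = km.smooth_resample(ramp, 9, 2, 10)
        assert np.allclose(prof.smoothed, ramp)
        assert len(prof.resampled) == 500

    def test_factor_one_is_identity_grid(self):
        series = np.sin(np.arange(30.0))
        prof = km.smooth_resample(series, 5, 2, 1)
        assert np.allclose(prof.resampled, prof.smoothed)

    def test_matches_explicit_least_squares_coefficients(self):
        """Interior smoothed values equal a direct per-window quadratic
        least-squares fit evaluated at the window center."""
        rng = np.random.default_rng(12)
        t = np.arange(100.0)
        noisy = np.sin(2 * np.pi * t / 25) + 0.1 * rng.standard_normal(100)
        prof = km.smooth_resample(noisy, 9, 2, 1)
        half = 4
        oracle = np.empty(100 - 2 * half)
        for i in range(half, 100 - half):
            w = np.arange(-half, half + 1, dtype=float)
            coeffs = np.polynomial.polynomial.polyfit(w, noisy[i - half: i + half + 1], 2)
            oracle[i - half] = coeffs[0]
        assert np.allclose(prof.smoothed[half:-half], oracle, atol=1e-10)

    def test_smoothing_reduces_noise_rms(self):
        rng = np.random.default_rng(13)
        t = np.arange(200.0)
        clean = np.sin(2 * np.pi * t / 40)
        noisy = clean + 0.1 * rng.standard_normal(200)
        prof = km.smooth_resample(noisy, 9, 2, 1)
        rms_before = np.sqrt(np.mean((noisy - clean) ** 2))
        rms_after = np.sqrt(np.mean((prof.smoothed - clean) ** 2))
        assert rms_after < rms_before

    @pytest.mark.parametrize("window,order", [(8, 2), (3, 3), (5, 5)])
    def test_bad_filter_config_rejected(self, window, order):
        with pytest.raises(ValueError):
            km.smooth_resample(np.arange(50.0), window, order, 10)


class TestDetectWaves:
    def test_pure_sine_amplitude_is_trough_to_peak(self):
        """100 + 50 sin(2 pi t / W): every amplitude equals 100."""
        W, n_waves = 24, 5
        prof = profile_from_fn(
            lambda t: 100 + 50 * np.sin(2 * np.pi * t / W), n_waves * W + 2
        )
        waves = km.detect_waves(prof, W, n_waves, 0)
        assert len(waves) == n_waves
        assert np.allclose(waves["amplitude"], 100.0, rtol=0.01)

    def test_monotone_window_zero_amplitude(self):
        prof = profile_from_fn(lambda t: t / 25.0, 26)
        waves = km.detect_waves(prof, 12, 2, 0)
        assert (waves["amplitude"] == 0.0).all()
        assert waves["trough"].isna().all()

    def test_flat_window_zero_amplitude(self):
        prof = profile_from_fn(lambda t: np.ones_like(t), 26)
        waves = km.detect_waves(prof, 12, 2, 0)
        assert (waves["amplitude"] == 0.0).all()

    def test_planted_alternation_within_ten_percent(self):
        amps = tuple([1.0, 0.4] * 7 + [1.0])
        kp = KymoSynthParams(
            amplitudes=amps, n_frames=16 * 24, frame_interval_min=2.5,
            noise_sd=0.02, seed=19,
        )
        kymo, planted = synthesize_kymograph(kp)
        waves = _extract_amplitudes(kymo, 24, 15)
        assert np.allclose(waves["amplitude"], planted, rtol=0.10)

    def test_truncation_warns(self):
        prof = profile_from_fn(lambda t: np.sin(2 * np.pi * t / 12), 49)
        with pytest.warns(UserWarning, match="truncating"):
            waves = km.detect_waves(prof, 12, 10, 0)
        assert len(waves) < 10

    def test_noiseless_round_trip_within_two_percent(self):
        """On a noiseless synthetic kymograph sampled at 24 frames/period,
        detected amplitudes equal planted ones within 2%."""
        rng = np.random.default_rng(23)
        amps = tuple(np.exp(0.3 * rng.standard_normal(15)))
        kp = KymoSynthParams(
            amplitudes=amps, n_frames=16 * 24, frame_interval_min=2.5, noise_sd=0.0
        )
        kymo, planted = synthesize_kymograph(kp)
        waves = _extract_amplitudes(kymo, 24, 15)
        assert np.allclose(waves["amplitude"], planted, rtol=0.02)

    def test_scale_and_shift_equivariance(self):
        amps = tuple([1.0, 0.4] * 7 + [1.0])
        kp = KymoSynthParams(
            amplitudes=amps, n_frames=16 * 24, frame_interval_min=2.5,
            noise_sd=0.02, seed=29,
        )
        kymo, _ = synthesize_kymograph(kp)
        base = _extract_amplitudes(kymo, 24, 15)["amplitude"].to_numpy()
        scaled = km.Kymograph(3.0 * kymo.data, kp.frame_interval_min, kp.px_size_um, 0)
        shifted = km.Kymograph(kymo.data + 55.0, kp.frame_interval_min, kp.px_size_um, 0)
        assert np.allclose(
            _extract_amplitudes(scaled, 24, 15)["amplitude"], 3.0 * base
        )
        assert np.allclose(
            _extract_amplitudes(shifted, 24, 15)["amplitude"], base
        )


class TestBoundaryAssignment:
    def test_wave_to_boundary_bijection(self):
        waves = pd.DataFrame({"wave_index": np.arange(1, 16), "amplitude": 1.0})
        out = km.assign_boundaries(waves)
        assert out.loc[out.wave_index == 1, "boundary_index"].item() == 11
        assert out.loc[out.wave_index == 15, "boundary_index"].item() == 25
        assert (out["boundary_index"] == out["wave_index"] + 10).all()


class TestNormalization:
    def _records(self, amps, phenos, exp="e1"):
        return pd.DataFrame(
            {"experiment_id": exp, "amplitude": amps, "phenotype": phenos}
        )

    def test_basic_normalization(self):
        rec = self._records([2.0, 2.0, 1.0], [0, 0, 1])
        out = km.normalize_amplitudes(rec)
        assert np.allclose(out["normalized_amplitude"], [1.0, 1.0, 0.5])

    def test_all_equal_amplitudes_normalize_to_one(self):
        rec = self._records([3.0] * 5, [0, 0, 1, 0, 1])
        out = km.normalize_amplitudes(rec)
        assert np.allclose(out["normalized_amplitude"], 1.0)

    def test_per_experiment_intact_mean_exactly_one(self):
        rng = np.random.default_rng(31)
        recs = pd.concat(
            [
                self._records(rng.uniform(1, 5, 10), rng.integers(0, 2, 10).tolist(), f"e{i}")
                for i in range(3)
            ],
            ignore_index=True,
        )
        out = km.normalize_amplitudes(recs)
        for _, grp in out.groupby("experiment_id"):
            intact = grp.loc[grp.phenotype == 0, "normalized_amplitude"]
            assert intact.mean() == pytest.approx(1.0, abs=1e-12)

    def test_no_intact_boundary_flagged(self):
        rec = self._records([1.0, 2.0], [1, 1])
        with pytest.warns(UserWarning, match="unnormalizable"):
            out = km.normalize_amplitudes(rec)
        assert out["normalized_amplitude"].isna().all()


class TestGroupComparison:
    def test_forty_percent_less(self):
        rec = pd.DataFrame(
            {
                "phenotype": [0, 0, 0, 1, 1, 1],
                "normalized_amplitude": [0.8, 1.0, 1.2, 0.5, 0.6, 0.7],
            }
        )
        rep = km.compare_amplitude_groups(rec)
        assert rep["percent_less"] == pytest.approx(40.0)

    def test_identical_groups_zero_difference(self):
        rec = pd.DataFrame(
            {"phenotype": [0, 0, 1, 1], "normalized_amplitude": [1.0, 2.0, 1.0, 2.0]}
        )
        rep = km.compare_amplitude_groups(rec)
        assert rep["percent_less"] == pytest.approx(0.0)

    def test_empty_group_named_in_error(self):
        rec = pd.DataFrame({"phenotype": [0, 0], "normalized_amplitude": [1.0, 2.0]})
        with pytest.raises(ValueError, match="defected"):
            km.compare_amplitude_groups(rec)
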