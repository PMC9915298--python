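"""Sphere-fit auto-calibration: window detection, fitting, recovery."""

import numpy as np
import pytest

import sedcut as sc
from sedcut.calibration import fit_calibration, find_stationary_windows


def unit_points(n=200, seed=0):
    """Roughly uniform unit vectors (good sphere coverage)."""
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def distorted_points(offset_mg, gain, n=200, noise_mg=2.0, seed=0):
    """Measured = gain * true + offset (+ noise), as a miscalibrated sensor."""
    rng = np.random.default_rng(seed)
    true = unit_points(n, seed)
    meas = true * np.asarray(gain) + np.asarray(offset_mg) / 1000.0
    return meas + rng.normal(0, noise_mg / 1000.0, meas.shape)


class TestStationaryWindows:
    def test_pure_noise_recording_returns_all_windows(self):
        rng = np.random.default_rng(0)
        samples = np.array([0, 0, 1.0]) + rng.normal(0, 0.003, (4000, 3))
        rec = sc.RawRecording("2023-03-06", 20.0, samples)
        pts = find_stationary_windows(rec, 10.0, 13.0)
        assert len(pts) == 4000 // 200

    def test_continuous_walking_yields_zero_windows(self):
        rec, _ = sc.generate_lab_recording(
            sc.lab_protocol_script(), sc.reference_lab_amplitudes(),
            sc.SensorSpec(noise_sd_mg=3.0), seed=2)
        # restrict to the walking bout (activity 8)
        script = sc.lab_protocol_script()
        b = next(x for x in script.bouts if x.code == 8)
        t0 = (b.start - rec.start_time).total_seconds()
        walk = sc.RawRecording(b.start, 20.0,
                               rec.slice_seconds(t0, t0 + 300))
        assert len(find_stationary_windows(walk, 10.0, 13.0)) == 0

    def test_window_means_match_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        # mixed: still block, moving block, still block
        parts = [np.array([1.0, 0, 0]) + rng.normal(0, 0.004, (1000, 3)),
                 rng.normal(0, 0.3, (1000, 3)),
                 np.array([0, -1.0, 0]) + rng.normal(0, 0.004, (1000, 3))]
        samples = np.vstack(parts)
        rec = sc.RawRecording("2023-03-06", 20.0, samples)
        got = find_stationary_windows(rec, 10.0, 13.0)
        # independent re-scan
        expect = []
        for i in range(0, 3000 - 199, 200):
            win = samples[i:i + 200]
            if (win.std(axis=0) < 0.013).all():
                expect.append(win.mean(axis=0))
        np.testing.assert_allclose(got, np.array(expect), atol=1e-12)

    def test_clipped_windows_excluded(self):
        samples = np.tile([0.0, 0.0, 1.0], (600, 1))
        samples[250:260, 2] = 4.0  # saturated
        rec = sc.RawRecording("2023-03-06", 20.0, samples, dynamic_range_g=4.0)
        pts = find_stationary_windows(rec, 10.0, 13.0)
        assert len(pts) == 2  # middle window dropped

    def test_empty_recording_rejected(self):
        rec = sc.RawRecording("2023-03-06", 20.0, np.ones((10, 3)))
        with pytest.raises(ValueError):
            find_stationary_windows(rec, 10.0, 13.0)


class TestFitCalibration:
    def test_perfect_points_give_identity(self):
        m = fit_calibration(unit_points())
        assert m.sphere_coverage_ok and m.converged
        np.testing.assert_allclose(m.gain, 1.0, atol=1e-6)
        np.testing.assert_allclose(m.offset_g, 0.0, atol=1e-6)
        assert m.post_error_g < 1e-6

    def test_recovers_injected_offsets_and_gains(self):
        offset = np.array([20.0, -30.0, 10.0])
        gain = np.array([1.02, 0.98, 1.00])
        m = fit_calibration(distorted_points(offset, gain, n=400))
        # ideal correction: gain' = 1/gain, offset' = -offset/gain
        np.testing.assert_allclose(m.gain, 1.0 / gain, atol=0.005)
        np.testing.assert_allclose(np.array(m.offset_g) * 1000,
                                   -offset / gain, atol=2.0)

    def test_median_offset_recovery_error_under_5mg(self):
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            offset = rng.uniform(-50, 50, 3)
            gain = rng.uniform(0.97, 1.03, 3)
            m = fit_calibration(distorted_points(offset, gain, seed=seed))
            errs.append(np.abs(np.array(m.offset_g) * 1000 - (-offset / gain)))
        assert np.median(np.concatenate(errs)) < 5.0

    def test_calibration_never_increases_post_error(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            pts = distorted_points(rng.uniform(-50, 50, 3),
                                   rng.uniform(0.97, 1.03, 3), seed=seed)
            err_identity = np.abs(np.linalg.norm(pts, axis=1) - 1).mean()
            m = fit_calibration(pts)
            assert m.post_error_g <= err_identity + 1e-12

    def test_refit_of_calibrated_points_is_idempotent(self):
        pts = distorted_points([20, -30, 10], [1.02, 0.98, 1.0], n=400)
        m1 = fit_calibration(pts)
        m2 = fit_calibration(m1.transform(pts))
        np.testing.assert_allclose(m2.gain, 1.0, atol=0.002)
        assert np.max(np.abs(m2.offset_g)) < 0.002

    def test_too_few_points_fall_back_to_identity(self):
        m = fit_calibration(unit_points(5))
        assert not m.converged and m.is_identity
        assert m.n_stationary_windows == 5

    def test_poor_sphere_coverage_falls_back_to_identity(self):
        # all points near +z: no sign coverage on any axis
        rng = np.random.default_rng(0)
        pts = np.array([0, 0, 1.0]) + rng.normal(0, 0.05, (100, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        m = fit_calibration(pts)
        assert not m.sphere_coverage_ok and not m.converged and m.is_identity


class TestApplyCalibration:
    def test_identity_model_leaves_recording_unchanged(self):
        rec = sc.RawRecording("2023-03-06", 20.0,
                              np.random.default_rng(0).normal(0, 1, (100, 3)))
        m = sc.CalibrationModel.identity(converged=True)
        out = sc.apply_calibration(rec, m)
        np.testing.assert_array_equal(out.samples, rec.samples)

    def test_apply_then_invert_round_trips(self):
        rec = sc.RawRecording("2023-03-06", 20.0,
                              np.random.default_rng(1).normal(0, 1, (100, 3)))
        m = sc.CalibrationModel((0.02, -0.01, 0.005), (1.02, 0.98, 1.0),
                                0.0, 50, True, True)
        out = sc.apply_calibration(rec, m)
        back = (out.samples - np.array(m.offset_g)) / np.array(m.gain)
        np.testing.assert_allclose(back, rec.samples, atol=1e-12)

    def test_unconverged_model_requires_force(self):
        rec = sc.RawRecording("2023-03-06", 20.0, np.ones((10, 3)))
        m = sc.CalibrationModel((0.01, 0, 0), (1.01, 1, 1), 0.0, 3, False,
                                False)
        with pytest.raises(ValueError, match="converge"):
            sc.apply_calibration(rec, m)
        out = sc.apply_calibration(rec, m, force=True)
        assert out.calibration is m


class TestEndToEnd:
    def test_freeliving_recording_calibrates_below_inclusion_criterion(
            self, small_freeliving):
        rec, _, sensor = small_freeliving
        cal, model = sc.AutoCalibration(rec).fit_apply()
        assert model.converged
        assert model.post_error_g < 0.01
        # stationary magnitudes sit within 0.01 g of 1 g after correction
        pts = find_stationary_windows(cal)
        mags = np.linalg.norm(pts, axis=1)
        assert np.abs(mags - 1).mean() < 0.01
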