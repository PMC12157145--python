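"""Functional calibration, strapdown integration, sensor fusion and Euler
decomposition."""

import dataclasses

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from monohip import (CycleROM, GaitSimConfig, OrientationSeries, TimeSeries,
                     complementary_orientation, euler_zyx,
                     functional_calibration, kalman_orientation,
                     rom_by_fusion, select_best_method, simulate_cohort,
                     strapdown_cycle_angle)
from monohip.calibration import GRAVITY

FS = 128.0


def _ts(values, fs=FS):
    return TimeSeries(np.arange(len(values)) / fs, np.asarray(values, float),
                      fs)


def _axis_error_deg(a, b):
    c = np.clip(abs(np.dot(a, b)), -1.0, 1.0)
    return np.degrees(np.arccos(c))


class TestFunctionalCalibration:
    def test_pure_y_rotation_recovers_y_axis(self):
        t = np.arange(1024) / FS
        gyro = np.zeros((len(t), 3))
        gyro[:, 1] = 100.0 * np.sin(2 * np.pi * 1.0 * t)
        # small out-of-plane component so the covariance has rank >= 2
        gyro[:, 0] = 0.1 * np.cos(2 * np.pi * 3.0 * t)
        cal = functional_calibration(_ts(gyro))
        assert _axis_error_deg(cal.ml_axis, [0.0, 1.0, 0.0]) < 0.1
        assert cal.pca_explained > 0.99

    def test_known_misalignment_recovered_noise_free(self,
                                                     noise_free_cohort):
        for trial in noise_free_cohort.trials[:8]:
            cal = functional_calibration(trial.imu.gyro_series())
            assert _axis_error_deg(cal.ml_axis, trial.ml_axis_true) < 0.5

    def test_flexion_sign_rule_points_axis_at_true_direction(
            self, noise_free_cohort):
        # not just the same line: the same direction (flexion positive)
        trial = noise_free_cohort.trials[0]
        cal = functional_calibration(trial.imu.gyro_series())
        assert np.dot(cal.ml_axis, trial.ml_axis_true) > 0.99

    def test_degenerate_covariance_rejected(self):
        gyro = np.zeros((512, 3))
        gyro[:, 1] = np.sin(np.arange(512) / 10.0)  # rank-1 motion
        with pytest.raises(ValueError, match="degenerate|rank"):
            functional_calibration(_ts(gyro))

    def test_rotation_is_proper_and_maps_ml_to_y(self, noise_free_cohort):
        trial = noise_free_cohort.trials[0]
        cal = functional_calibration(trial.imu.gyro_series())
        np.testing.assert_allclose(cal.rotation @ cal.rotation.T,
                                   np.eye(3), atol=1e-10)
        assert np.linalg.det(cal.rotation) == pytest.approx(1.0)
        np.testing.assert_allclose(cal.rotation @ cal.ml_axis,
                                   [0.0, 1.0, 0.0], atol=1e-10)

    def test_calibration_equivariance_under_sensor_rotation(
            self, noise_free_cohort):
        # rotating the raw gyro by any proper rotation and re-calibrating
        # must leave the sagittal (medio-lateral) projection unchanged
        trial = noise_free_cohort.trials[0]
        gyro = trial.imu.gyro_series()
        R = Rotation.from_rotvec(np.deg2rad(35.0) * np.array(
            [0.4, -0.7, 0.59])).as_matrix()
        rotated = _ts(gyro.values @ R.T)
        cal0 = functional_calibration(gyro)
        cal1 = functional_calibration(rotated)
        proj0 = gyro.values @ cal0.ml_axis
        proj1 = rotated.values @ cal1.ml_axis
        assert np.abs(proj0 - proj1).max() < 0.5


class TestStrapdown:
    def test_constant_rate_rectangle_integral(self):
        w = np.full(int(FS) + 1, 10.0)
        angle, rom = strapdown_cycle_angle(w, FS)
        assert angle[-1] == pytest.approx(10.0, abs=1e-6)
        assert rom == pytest.approx(10.0, abs=1e-6)

    def test_cosine_rate_closed_form(self):
        # omega(t) = 100 cos(2 pi t): angle = (100 / 2 pi) sin(2 pi t),
        # range = 200 / 2 pi = 31.83 deg
        t = np.arange(int(FS)) / FS
        _, rom = strapdown_cycle_angle(100.0 * np.cos(2 * np.pi * t), FS)
        assert rom == pytest.approx(200.0 / (2 * np.pi), abs=0.05)

    def test_zero_signal_zero_rom(self):
        _, rom = strapdown_cycle_angle(np.zeros(100), FS)
        assert rom == 0.0

    def test_too_short_cycle_rejected(self):
        with pytest.raises(ValueError):
            strapdown_cycle_angle(np.array([1.0]), FS)

    def test_per_cycle_restart_keeps_error_flat_over_long_trials(self):
        # 60 noisy cycles: |ROM error| must not grow with cycle index
        cfg = dataclasses.replace(
            GaitSimConfig(n_participants=1, sides=("L",),
                          trials_per_participant=1, cycles_per_trial=60,
                          seed=9),
            gyro_noise_sd=2.0, sta_amp=5.0)
        trial = simulate_cohort(cfg).trials[0]
        cal = functional_calibration(trial.imu.gyro_series())
        ml = trial.imu.gyro @ cal.ml_axis
        idx = np.searchsorted(trial.imu.t, trial.events)
        errors = []
        for c, (i0, i1) in enumerate(zip(idx[:-1], idx[1:])):
            _, rom = strapdown_cycle_angle(ml[i0:i1], FS)
            errors.append(abs(rom - trial.truth["thigh_rom"].iloc[c]))
        slope = np.polyfit(np.arange(60), errors, 1)[0]
        assert abs(slope) < 0.01  # deg per cycle


class TestComplementaryFilter:
    def test_static_level_sensor_stays_identity(self):
        n = int(FS * 2)
        g = _ts(np.zeros((n, 3)))
        a = _ts(np.tile([0.0, 0.0, GRAVITY], (n, 1)))
        q = complementary_orientation(g, a, gain=0.02)
        ang, _ = euler_zyx(q)
        assert np.abs(ang).max() < 1e-9

    def test_gyro_only_constant_rate_integrates_to_ninety(self):
        n = int(FS * 1) + 1
        g = np.zeros((n, 3))
        g[:, 1] = 90.0
        th = np.deg2rad(90.0 * np.arange(n) / FS)
        a = np.column_stack([-GRAVITY * np.sin(th), np.zeros(n),
                             GRAVITY * np.cos(th)])
        q = complementary_orientation(_ts(g), _ts(a), gain=0.0)
        ang, _ = euler_zyx(q)
        assert ang[-1, 1] == pytest.approx(90.0, abs=0.1)

    def test_accel_correction_bounds_gyro_bias_drift(self):
        n = int(FS * 10) + 1
        g = np.zeros((n, 3))
        g[:, 1] = 1.0  # 1 deg/s bias
        a = np.tile([0.0, 0.0, GRAVITY], (n, 1))
        drift = euler_zyx(complementary_orientation(
            _ts(g), _ts(a), gain=0.0))[0][-1, 1]
        held = euler_zyx(complementary_orientation(
            _ts(g), _ts(a), gain=0.02))[0][-1, 1]
        assert drift == pytest.approx(10.0, abs=0.1)
        assert abs(held) < 2.0

    def test_quaternions_stay_unit_norm(self):
        rng = np.random.default_rng(2)
        n = int(FS * 3)
        g = _ts(rng.normal(0, 50, size=(n, 3)))
        a = _ts(np.tile([0.0, 0.0, GRAVITY], (n, 1)))
        q = complementary_orientation(g, a, gain=0.05)
        np.testing.assert_allclose(
            np.linalg.norm(q.quaternions, axis=1), 1.0, atol=1e-9)


class TestKalmanFilter:
    def test_static_no_noise_identity(self):
        n = int(FS * 2)
        g = _ts(np.zeros((n, 3)))
        a = _ts(np.tile([0.0, 0.0, GRAVITY], (n, 1)))
        ang, _ = euler_zyx(kalman_orientation(g, a))
        assert np.abs(ang).max() < 1e-6

    def test_infinite_measurement_noise_matches_pure_gyro(self):
        rng = np.random.default_rng(5)
        n = int(FS * 5)
        g = _ts(rng.normal(0.0, 30.0, size=(n, 3)))
        a = _ts(np.tile([0.0, 0.0, GRAVITY], (n, 1)))
        qk = kalman_orientation(g, a, gyro_noise_sd=1.0,
                                accel_noise_sd=1e9)
        qg = complementary_orientation(g, a, gain=0.0)
        ang_k, _ = euler_zyx(qk)
        ang_g, _ = euler_zyx(qg)
        assert np.abs(ang_k - ang_g).max() < 0.2

    def test_tilt_error_beats_pure_gyro_under_noise(self):
        kal_err, gyro_err = [], []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(FS * 5)
            g = _ts(rng.normal(0.0, 2.0, size=(n, 3)))
            a = _ts(np.tile([0.0, 0.0, GRAVITY], (n, 1))
                    + rng.normal(0.0, 0.05, size=(n, 3)))
            for store, q in ((kal_err, kalman_orientation(
                    g, a, gyro_noise_sd=2.0, accel_noise_sd=0.05)),
                    (gyro_err, complementary_orientation(g, a, gain=0.0))):
                ang, _ = euler_zyx(q)
                store.append(np.abs(ang[-1, 1:]).max())
        assert np.mean(kal_err) < np.mean(gyro_err)

    def test_non_positive_noise_rejected(self):
        n = 16
        g = _ts(np.zeros((n, 3)))
        a = _ts(np.tile([0.0, 0.0, GRAVITY], (n, 1)))
        with pytest.raises(ValueError):
            kalman_orientation(g, a, gyro_noise_sd=0.0)


class TestEulerZYX:
    def test_identity_quaternion(self):
        q = OrientationSeries(np.array([[1.0, 0, 0, 0]]), FS)
        ang, flags = euler_zyx(q)
        np.testing.assert_allclose(ang, 0.0, atol=1e-12)
        assert not flags.any()

    def test_pure_z_rotation(self):
        r = Rotation.from_euler("Z", 90.0, degrees=True)
        q = OrientationSeries(r.as_quat(scalar_first=True)[None, :], FS)
        ang, _ = euler_zyx(q)
        np.testing.assert_allclose(ang[0], [90.0, 0.0, 0.0], atol=1e-9)

    def test_round_trip_through_rotation_matrix(self):
        rng = np.random.default_rng(11)
        rots = Rotation.random(500, rng=rng)
        q = OrientationSeries(rots.as_quat(scalar_first=True), FS)
        ang, flags = euler_zyx(q)
        ok = ~flags
        back = Rotation.from_euler("ZYX", ang[ok], degrees=True)
        err = (back * rots[ok].inv()).magnitude()
        assert np.degrees(err).max() < 1e-6


class TestRomByFusion:
    def test_zero_motion_zero_rom(self):
        n = int(FS * 2)
        q = OrientationSeries(np.tile([1.0, 0, 0, 0], (n, 1)), FS)
        cal = _identity_cal()
        out = rom_by_fusion(q, cal, np.array([0.0, 1.0, 2.0 - 0.5 / FS]))
        assert [c.thigh_rom for c in out] == [0.0, 0.0]

    def test_single_axis_sinusoid_closed_form(self):
        # pitch = A sin(2 pi t): per-cycle ROM = 2A
        A = 20.0
        n = int(FS * 2)
        t = np.arange(n) / FS
        rots = Rotation.from_euler(
            "Y", (A * np.sin(2 * np.pi * t))[:, None], degrees=True)
        q = OrientationSeries(rots.as_quat(scalar_first=True), FS)
        out = rom_by_fusion(q, _identity_cal(),
                            np.array([0.0, 1.0, 2.0 - 0.5 / FS]))
        for c in out:
            assert c.thigh_rom == pytest.approx(2 * A, abs=0.05)


def _identity_cal():
    from monohip import SegmentCalibration
    return SegmentCalibration(np.eye(3), np.array([0.0, 1.0, 0.0]), 0.9)


class TestSelectBestMethod:
    def test_exact_method_wins(self):
        ref = np.array([30.0, 32.0, 31.0])
        cands = {
            "kalman": [CycleROM(i, v + 2.0, "kalman")
                       for i, v in enumerate(ref)],
            "strapdown": [CycleROM(i, v, "strapdown")
                          for i, v in enumerate(ref)],
        }
        best, table = select_best_method(cands, ref)
        assert best == "strapdown"
        assert table.set_index("method").loc["strapdown", "mae"] == 0.0

    def test_tie_broken_by_canonical_order(self):
        ref = np.array([30.0, 32.0, 31.0])
        cands = {m: ref.copy() for m in ("kalman", "complementary",
                                         "strapdown")}
        best, _ = select_best_method(cands, ref)
        assert best == "strapdown"

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_best_method({}, np.array([1.0]))

    def test_selected_method_has_minimal_mae(self, noise_free_cohort):
        trial = noise_free_cohort.trials[0]
        from monohip.pipeline import compute_trial_rom
        ref = trial.truth["thigh_rom"].to_numpy()
        df = compute_trial_rom(trial.imu, trial.events, method="auto",
                               reference=ref)
        chosen_mae = np.mean(np.abs(df["thigh_rom"].to_numpy() - ref))
        for m in ("strapdown", "complementary", "kalman"):
            other = compute_trial_rom(trial.imu, trial.events, method=m)
            mae = np.mean(np.abs(other["thigh_rom"].to_numpy() - ref))
            assert chosen_mae <= mae + 1e-12
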