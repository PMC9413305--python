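"""Kick metrics, resampling, RMSE and Bland–Altman agreement."""

import numpy as np
import pytest

from kicktrack import (AlignmentError, KickTrackError, KinematicTrack,
                       PhaseDetectionError, backswing_height, bland_altman,
                       extract_metrics, max_speed, motion_onset, path_length,
                       resample_to_reference, trajectory_rmse)


def make_track(pos, vel=None, dt=0.01) -> KinematicTrack:
    pos = np.asarray(pos, dtype=float)
    n = len(pos)
    if vel is None:
        vel = np.vstack([np.zeros(3),
                         np.diff(pos, axis=0) / dt]) if n > 1 \
            else np.zeros((n, 3))
    return KinematicTrack(accel=np.zeros((n, 3)), vel=np.asarray(vel, float),
                          pos=pos, stationary=np.zeros(n, bool), dt=dt)


class TestPathLength:
    def test_static_track_zero(self):
        assert path_length(make_track(np.zeros((10, 3)))) == 0.0

    def test_straight_line(self):
        pos = np.column_stack([np.linspace(0, 1, 11),
                               np.zeros(11), np.zeros(11)])
        assert path_length(make_track(pos)) == pytest.approx(1.0)

    def test_semicircle_chord_sum(self):
        theta = np.deg2rad(np.arange(0, 181))
        pos = np.column_stack([np.cos(theta), np.sin(theta),
                               np.zeros_like(theta)])
        assert path_length(pos) == pytest.approx(np.pi, abs=1e-4)

    def test_rotation_invariance(self, rng):
        pos = rng.normal(0, 1, (40, 3))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        assert path_length(pos @ q.T) == pytest.approx(path_length(pos))

    def test_at_least_straight_line_distance(self, rng):
        pos = rng.normal(0, 1, (25, 3))
        assert path_length(pos) >= np.linalg.norm(pos[-1] - pos[0]) - 1e-12


class TestMaxSpeed:
    def test_zero_track(self):
        speed, idx, pos = max_speed(make_track(np.zeros((5, 3))))
        assert speed == 0.0 and idx == 0
        np.testing.assert_array_equal(pos, [0, 0, 0])

    def test_ramp_peaks_at_last_sample(self):
        t = np.arange(20) * 0.01
        vel = np.column_stack([t, np.zeros_like(t), np.zeros_like(t)])
        track = make_track(np.zeros((20, 3)), vel=vel)
        speed, idx, _ = max_speed(track)
        assert idx == 19 and speed == pytest.approx(t[-1])

    def test_tie_resolves_to_earliest(self):
        vel = np.zeros((10, 3))
        vel[[3, 7], 0] = 2.0
        _, idx, _ = max_speed(make_track(np.zeros((10, 3)), vel=vel))
        assert idx == 3

    def test_concatenation_max(self, rng):
        v1, v2 = rng.normal(0, 1, (30, 3)), rng.normal(0, 1, (20, 3))
        t1 = make_track(np.zeros((30, 3)), vel=v1)
        t2 = make_track(np.zeros((20, 3)), vel=v2)
        both = make_track(np.zeros((50, 3)), vel=np.vstack([v1, v2]))
        assert max_speed(both)[0] == pytest.approx(
            max(max_speed(t1)[0], max_speed(t2)[0]))


class TestBackswingHeight:
    def test_no_preceding_samples_is_error(self):
        vel = np.zeros((10, 3))
        vel[0, 0] = 5.0  # speed peaks immediately: no backswing phase
        with pytest.raises(PhaseDetectionError):
            backswing_height(make_track(np.zeros((10, 3)), vel=vel))

    def test_synthetic_arc_apex(self):
        t = np.linspace(0, 1, 101)
        z = 0.756 * np.sin(np.pi * t) ** 2
        pos = np.column_stack([np.zeros_like(t), t, z])
        vel = np.zeros((101, 3))
        vel[-1, 1] = 9.0  # peak speed at the end
        h, idx = backswing_height(make_track(pos, vel=vel))
        assert h == pytest.approx(0.756, abs=1e-9)
        assert idx == 50

    def test_flat_then_kick_is_nonnegative(self):
        pos = np.zeros((50, 3))
        vel = np.zeros((50, 3))
        vel[40, 1] = 7.0
        h, _ = backswing_height(make_track(pos, vel=vel))
        assert h >= 0.0

    def test_apex_measured_relative_to_start(self):
        pos = np.zeros((30, 3))
        pos[:, 2] = 1.5                     # track starts elevated
        pos[10, 2] = 2.1
        vel = np.zeros((30, 3)); vel[25, 1] = 5.0
        h, idx = backswing_height(make_track(pos, vel=vel))
        assert h == pytest.approx(0.6) and idx == 10


def test_extract_metrics_degenerate_static_track():
    met = extract_metrics(make_track(np.zeros((20, 3))))
    assert met.max_speed == 0.0 and met.backswing_height == 0.0


class TestResample:
    def test_identical_rates_identity(self, rng):
        pos = rng.normal(0, 1, (40, 3))
        t = np.arange(40) * 0.01
        imu, ref, tt = resample_to_reference(t, pos, t, pos)
        np.testing.assert_allclose(imu, pos, atol=1e-12)
        assert len(tt) == 40

    def test_half_rate_pairs_every_other_sample(self, rng):
        pos = rng.normal(0, 1, (40, 3))
        t = np.arange(40) * 0.01
        imu, ref, _ = resample_to_reference(t, pos, t[::2], pos[::2])
        np.testing.assert_allclose(imu, pos[::2], atol=1e-12)

    def test_linear_trajectory_interpolates_exactly(self):
        t_imu = np.arange(0, 1.0, 1 / 100)
        t_ref = np.arange(0, 0.995, 1 / 240)
        pos = np.column_stack([2 * t_imu, -t_imu, np.zeros_like(t_imu)])
        expect = np.column_stack([2 * t_ref, -t_ref, np.zeros_like(t_ref)])
        imu, ref, _ = resample_to_reference(t_imu, pos, t_ref, expect)
        np.testing.assert_allclose(imu, ref, atol=1e-12)
        assert len(imu) == np.sum(t_ref <= t_imu[-1])

    def test_disjoint_spans_rejected(self):
        t1 = np.arange(10) * 0.01
        t2 = t1 + 100.0
        pos = np.zeros((10, 3))
        with pytest.raises(AlignmentError):
            resample_to_reference(t1, pos, t2, pos)

    def test_onset_alignment_recovers_shift(self):
        dt = 0.01
        t = np.arange(300) * dt
        z = np.zeros_like(t)
        z[100:] = np.minimum(1.0, (t[100:] - t[100])) ** 2
        pos = np.column_stack([np.zeros_like(t), z, np.zeros_like(t)])
        # reference starts mid-lead: same motion but clock offset by 0.5 s
        imu, ref, _ = resample_to_reference(t, pos, t[:250] - 0.5, pos[50:],
                                            align="onset")
        assert np.abs(imu - ref).max() < 0.05


class TestTrajectoryRmse:
    def test_identical_is_zero(self, rng):
        pos = rng.normal(0, 1, (30, 3))
        assert trajectory_rmse(pos, pos)[0] == 0.0

    def test_constant_offset(self, rng):
        pos = rng.normal(0, 1, (30, 3))
        shifted = pos + np.array([0.1, 0.0, 0.0])
        assert trajectory_rmse(pos, shifted)[0] == pytest.approx(0.1)

    def test_gaussian_perturbation_gives_sigma_sqrt3(self, rng):
        # E[rmse^2] = 3 sigma^2 for iid per-axis noise
        sigma = 0.2
        pos = np.zeros((20000, 3))
        noisy = pos + rng.normal(0, sigma, pos.shape)
        rmse, _ = trajectory_rmse(pos, noisy)
        assert rmse == pytest.approx(sigma * np.sqrt(3), rel=0.02)

    def test_velocity_rmse_along_direction(self):
        v_a = np.tile([0.0, 2.0, 0.0], (10, 1))
        v_b = np.tile([0.0, 1.5, 3.0], (10, 1))
        pos = np.zeros((10, 3))
        _, vrmse = trajectory_rmse(pos, pos, v_a, v_b,
                                   direction=[0.0, 1.0, 0.0])
        assert vrmse == pytest.approx(0.5)


class TestBlandAltman:
    def test_identical_data_collapses_limits(self, rng):
        x = rng.normal(0, 1, (50, 3))
        for ax in bland_altman(x, x):
            assert ax.bias == 0.0
            assert ax.loa_low == ax.loa_high == 0.0
            assert ax.n_outside == 0

    def test_constant_offset_becomes_bias(self, rng):
        x = rng.normal(0, 1, (100,))
        stats = bland_altman(x + 0.3, x)[0]
        assert stats.bias == pytest.approx(0.3)
        assert stats.loa_high - stats.bias == pytest.approx(
            stats.bias - stats.loa_low)

    def test_gaussian_differences_five_percent_outside(self, rng):
        d = rng.normal(0, 1.0, (5000,))
        stats = bland_altman(d, np.zeros_like(d))[0]
        assert stats.fraction_outside == pytest.approx(0.05, abs=0.01)

    def test_too_few_pairs(self):
        with pytest.raises(KickTrackError):
            bland_altman(np.zeros(2), np.zeros(2))


def test_motion_onset_detects_sustained_movement():
    dt = 0.01
    t = np.arange(400) * dt
    pos = np.zeros((400, 3))
    pos[200:, 1] = (t[200:] - t[200]) * 2.0   # 2 m/s from t = 2 s
    assert motion_onset(t, pos) == pytest.approx(2.0, abs=0.05)
    with pytest.raises(AlignmentError):
        motion_onset(t, np.zeros((400, 3)))
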