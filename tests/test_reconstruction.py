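"""Gravity removal, leveling, gating, integration and the full chain."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kicktrack import (DegenerateAttitudeError, G_STD, KickProfile,
                       KickTrackError, NoiseModel, PipelineConfig,
                       StaticOffset, apply_tilt, compensate_gravity,
                       estimate_static_offset, gate_acceleration,
                       integrate_track, reconstruct, simulate_kick,
                       tilt_correction)


class TestStaticOffset:
    def test_constant_stream(self):
        accels = np.tile([0.0, 0.0, G_STD], (600, 1))
        off = estimate_static_offset(accels, 500)
        np.testing.assert_allclose(off.offset_accl, [0, 0, G_STD])

    def test_noise_averages_out(self, rng):
        sigma = 0.01
        accels = np.tile([0.0, 0.0, G_STD], (600, 1)) \
            + rng.normal(0, sigma, (600, 3))
        off = estimate_static_offset(accels, 500)
        err = np.abs(off.offset_accl - [0, 0, G_STD])
        assert np.all(err < 3 * sigma / np.sqrt(500))

    def test_window_one_returns_first_sample(self):
        accels = np.array([[1.0, 2.0, 9.0], [4.0, 5.0, 6.0]])
        with pytest.warns(UserWarning):  # norm far from 1 g
            off = estimate_static_offset(accels, 1)
        np.testing.assert_array_equal(off.offset_accl, accels[0])

    def test_short_stream_rejected(self):
        with pytest.raises(KickTrackError):
            estimate_static_offset(np.zeros((100, 3)), 500)


def test_compensate_gravity():
    off = StaticOffset(offset_accl=np.array([0.0, 0.0, 3.0]))
    out = compensate_gravity(np.array([[1.0, 2.0, 3.0]]), off)
    np.testing.assert_array_equal(out, [[1.0, 2.0, 0.0]])


class TestTiltCorrection:
    def test_level_sensor_gives_identity(self):
        tilt = tilt_correction(StaticOffset(np.array([0.0, 0.0, G_STD])))
        assert tilt.roll == tilt.pitch == tilt.yaw == 0.0
        np.testing.assert_allclose(tilt.trotate, np.eye(3), atol=1e-15)

    def test_pure_roll_recovered(self):
        ang = np.deg2rad(10.0)
        off = StaticOffset(G_STD * np.array([0.0, np.sin(ang),
                                             np.cos(ang)]))
        tilt = tilt_correction(off)
        assert tilt.roll == pytest.approx(ang)
        corrected = tilt.trotate @ off.offset_accl
        np.testing.assert_allclose(corrected[:2], 0.0, atol=1e-12)
        assert corrected[2] == pytest.approx(G_STD)

    def test_random_tilts_align_gravity(self, rng):
        for _ in range(50):
            axis = np.array([*rng.normal(size=2), 0.0])
            axis /= np.linalg.norm(axis)
            ang = rng.uniform(0, np.deg2rad(15))
            c, s = np.cos(ang), np.sin(ang)
            k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                          [-axis[1], axis[0], 0]])
            rot = np.eye(3) + s * k + (1 - c) * (k @ k)
            off = StaticOffset(rot.T @ np.array([0.0, 0.0, G_STD]))
            tilt = tilt_correction(off)
            corrected = tilt.trotate @ off.offset_accl
            assert np.abs(corrected[:2]).max() < 1e-9 * G_STD
            assert np.linalg.det(tilt.trotate) == pytest.approx(1.0)
            np.testing.assert_allclose(tilt.trotate @ tilt.trotate.T,
                                       np.eye(3), atol=1e-12)

    def test_small_angle_variant_matches_stated_formula(self):
        off = StaticOffset(np.array([1.0, 2.0, 9.0]))
        tilt = tilt_correction(off, exact=False)
        assert tilt.pitch == pytest.approx(-np.arctan(1.0 / 9.0))
        assert tilt.roll == pytest.approx(np.arctan2(2.0, 9.0))

    def test_sideways_sensor_rejected(self):
        with pytest.raises(DegenerateAttitudeError):
            tilt_correction(StaticOffset(np.array([G_STD, 0.0, 0.0])))


def test_apply_tilt_rotates_and_preserves_norms(rng):
    ninety_roll = tilt_correction(
        StaticOffset(np.array([0.0, G_STD * np.sin(np.pi / 4),
                               G_STD * np.cos(np.pi / 4)])))
    # a 45-deg roll matrix applied twice maps y to z
    twice = ninety_roll.trotate @ ninety_roll.trotate
    np.testing.assert_allclose(twice @ [0.0, 1.0, 0.0], [0.0, 0.0, 1.0],
                               atol=1e-12)
    vecs = rng.normal(0, 5, (30, 3))
    out = apply_tilt(vecs, ninety_roll)
    np.testing.assert_allclose(np.linalg.norm(out, axis=1),
                               np.linalg.norm(vecs, axis=1), rtol=1e-12)


class TestGate:
    def test_below_gate_zeroed(self):
        out = gate_acceleration(np.array([[0.1, 0.0, 0.0]]), 0.392)
        np.testing.assert_array_equal(out, [[0.0, 0.0, 0.0]])

    def test_above_gate_untouched(self):
        out = gate_acceleration(np.array([[5.0, 0.0, 0.0]]), 0.392)
        np.testing.assert_array_equal(out, [[5.0, 0.0, 0.0]])

    def test_zero_gate_is_identity(self, rng):
        a = rng.normal(0, 1, (20, 3))
        np.testing.assert_array_equal(gate_acceleration(a, 0.0), a)

    @settings(derandomize=True, max_examples=40)
    @given(st.lists(st.lists(st.floats(-10, 10), min_size=3, max_size=3),
                    min_size=1, max_size=30),
           st.floats(0, 5))
    def test_never_increases_magnitude(self, accels, gate):
        a = np.asarray(accels)
        out = gate_acceleration(a, gate)
        assert np.all(np.linalg.norm(out, axis=1)
                      <= np.linalg.norm(a, axis=1) + 1e-12)


class TestIntegrateTrack:
    def test_trapezoid_exact_for_constant_accel(self, config):
        a = np.tile([1.0, 0.0, 0.0], (101, 1))
        track = integrate_track(a, config)
        assert track.vel[100, 0] == pytest.approx(1.0, abs=1e-12)

    def test_trapezoid_exact_for_linear_accel(self, config):
        t = np.arange(101) * config.dt
        a = np.column_stack([2.0 * t, np.zeros_like(t), np.zeros_like(t)])
        track = integrate_track(a, config)
        # v(1) = int_0^1 2t dt = 1 exactly under the averaged-sample rule
        assert track.vel[100, 0] == pytest.approx(1.0, abs=1e-12)

    def test_initial_conditions(self, config):
        track = integrate_track(np.ones((10, 3)), config)
        np.testing.assert_array_equal(track.vel[0], 0.0)
        np.testing.assert_array_equal(track.pos[0], 0.0)

    def test_zupt_zeroes_velocity_after_run(self, config):
        """An acceleration burst followed by 15 gated zeros must end with
        exactly zero velocity and a frozen position."""
        a = np.zeros((60, 3))
        a[20:25, 0] = 5.0
        track = integrate_track(a, config)
        assert np.any(track.vel[:, 0] > 0)
        trigger = 25 + config.zupt_run_length - 1
        assert np.all(track.vel[trigger:] == 0.0)
        assert np.all(track.stationary[trigger:])
        assert np.all(track.pos[trigger:] == track.pos[trigger])

    def test_zupt_idempotent_until_new_motion(self, config):
        a = np.zeros((120, 3))
        a[20:25, 0] = 5.0
        a[90:95, 1] = -4.0
        track = integrate_track(a, config)
        assert np.all(track.vel[40:90] == 0.0)
        assert np.any(track.vel[91:, 1] != 0.0)  # motion resumes

    def test_velocity_before_detection_persists(self, config):
        # inside the 15-sample detection latency the velocity plateau remains
        a = np.zeros((40, 3))
        a[5:10, 0] = 5.0
        track = integrate_track(a, config)
        plateau = track.vel[11:5 + 5 + config.zupt_run_length - 1, 0]
        assert np.all(plateau == plateau[0]) and plateau[0] > 0


class TestReconstruct:
    def test_pure_static_stream_stays_at_origin(self, config):
        profile = KickProfile(path_length_target=0.0)
        _, sim = simulate_kick(profile, NoiseModel.randomized(7), config)
        track = reconstruct(sim.stream, None, config)
        assert np.linalg.norm(track.pos, axis=1).max() < 1e-6

    def test_zero_noise_round_trip(self, noiseless_kick):
        """With a perfect sensor the reconstruction error is attitude
        truncation only: position RMSE under 1 cm over the whole kick."""
        _, truth, sim = noiseless_kick
        track = reconstruct(sim.stream)
        d = track.pos - truth.pos
        rmse = np.sqrt(np.mean(np.sum(d ** 2, axis=1)))
        assert rmse < 0.01

    def test_terminal_velocity_zero_after_landing(self, noiseless_kick):
        _, truth, sim = noiseless_kick
        track = reconstruct(sim.stream)
        assert np.all(track.vel[-50:] == 0.0)
        assert np.all(track.stationary[-50:])

    def test_error_shrinks_with_rate(self):
        """Halving dt cuts the zero-noise position error by ~4x (attitude
        truncation is second order in the step)."""
        rmse = {}
        for rate in (100.0, 200.0):
            cfg = PipelineConfig(sample_rate_hz=rate,
                                 static_window=int(5 * rate),
                                 zupt_run_length=round(0.15 * rate))
            profile = KickProfile(static_lead=int(6 * rate),
                                  static_tail=int(1.5 * rate))
            truth, sim = simulate_kick(profile, NoiseModel.noiseless(), cfg)
            track = reconstruct(sim.stream, None, cfg)
            d = track.pos - truth.pos
            rmse[rate] = np.sqrt(np.mean(np.sum(d ** 2, axis=1)))
        assert rmse[200.0] < 0.5 * rmse[100.0]
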