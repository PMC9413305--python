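"""Synthetic instep-kick generator: analytic truth and raw IMU inversion.

The simulator makes every pipeline stage testable without recorded data.  It
builds a smooth (C^2) ground-truth foot trajectory for an instep kick — a
long stationary lead-in, a backswing arcing up to the commanded apex height,
a forward swing whose speed peaks at the commanded value as the foot passes
its lowest point, and a decelerating follow-through to rest — then inverts
the kinematics into what the strapped-on sensor would have measured: the
specific force ``R_ws^T (a + g z)`` and body rates in the (optionally
tilted) sensor frame, pushed through the accelerometer deviation model
``measured = L (true + b)``, plus Gaussian noise and 16-bit quantization at
the configured full-scale ranges.

Trajectory construction.  Per-axis segments are built from the quintic
smoothstep ``s(u) = 6u^5 - 15u^4 + 10u^3`` (zero velocity *and* acceleration
at both ends, so segment joins are C^2) and, for the forward swing, a
``sin^2`` speed pulse whose maximum is the commanded peak speed exactly.  At
the peak-speed instant the vertical and lateral rates vanish by
construction, so the commanded peak is the exact maximum of the speed
profile; the apex height is hit exactly at the end of the backswing.  The
forward-swing displacement is solved (by root finding on the analytic path
integral) so that the total path length meets the commanded target; phase
durations are snapped to the sample grid, which perturbs the path length by
at most one sample's travel (well under the 2% construction tolerance).

Default profile values reproduce the study conditions this package targets:
path about 3.63 m, peak foot speed 7.47 m/s, backswing apex 0.756 m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from scipy.optimize import brentq

from .attitude import quat_conjugate, quat_from_axis_angle, quat_multiply, \
    rotate_by_quaternion
from .calibration import fit_sphere
from .io import (G_STD, ImuStream, PipelineConfig, ProfileError,
                 RawImuSample, accel_lsb, encode_counts, gyro_lsb)
from .metrics import extract_metrics, kick_direction
from .reconstruction import reconstruct

_COUNT_HALF = 32768


# ---------------------------------------------------------------------------
# quintic smoothstep
# ---------------------------------------------------------------------------

def _s(u):
    """Quintic smoothstep: s(0)=0, s(1)=1, s'=s''=0 at both ends."""
    return u ** 3 * (10.0 - 15.0 * u + 6.0 * u ** 2)


def _sp(u):
    return 30.0 * u ** 2 * (1.0 - u) ** 2


def _spp(u):
    return 60.0 * u * (1.0 - u) * (1.0 - 2.0 * u)


# ---------------------------------------------------------------------------
# profiles
# ---------------------------------------------------------------------------

@dataclass
class KickProfile:
    """Commanded geometry and timing of a synthetic instep kick.

    ``backswing_height`` (m), ``peak_speed`` (m/s) and
    ``path_length_target`` (m) are met by construction (the path to within
    2%, from grid snapping).  ``kick_duration`` is the total moving time
    (backswing + forward swing), s; the forward-swing duration follows from
    the solved displacement and the commanded peak speed, and the backswing
    gets the remainder.  ``static_lead``/``static_tail`` are stationary
    sample counts before and after the motion.  ``orientation_sweep`` is the
    total foot-pitch rotation over the kick, rad.  ``backswing_distance`` is
    the horizontal pull-back (m), ``follow_through_height`` the final foot
    height (m) and ``lateral_amplitude`` the sideways excursion (m) of the
    swing plane.
    """

    backswing_height: float = 0.756
    peak_speed: float = 7.47
    path_length_target: float = 3.63
    kick_duration: float = 1.5
    static_lead: int = 600
    orientation_sweep: float = np.deg2rad(60.0)
    backswing_distance: float = 0.35
    follow_through_height: float = 0.25
    lateral_amplitude: float = 0.05
    static_tail: int = 150

    def __post_init__(self) -> None:
        for name in ("backswing_height", "peak_speed", "path_length_target",
                     "kick_duration", "backswing_distance",
                     "follow_through_height", "lateral_amplitude"):
            if getattr(self, name) < 0:
                raise ProfileError(f"{name} must be non-negative")
        if self.static_lead < 1:
            raise ProfileError("static_lead must be positive")
        if self.static_tail < 1:
            raise ProfileError("static_tail must be positive")


@dataclass
class NoiseModel:
    """Sensor imperfections applied when inverting the truth into readings.

    ``accel_sigma`` (m/s^2) and ``gyro_sigma`` (rad/s) are per-axis Gaussian
    noise levels; ``accel_bias`` (g) and ``accel_scale`` (dimensionless) are
    the deviation-model parameters the calibration stage must recover;
    ``gyro_bias`` (rad/s) is subtracted downstream from the static window;
    ``initial_tilt`` tilts the mounted sensor about a horizontal axis at
    ``tilt_azimuth``.  All randomness flows from ``seed``.
    """

    accel_sigma: float = 0.05
    gyro_sigma: float = np.deg2rad(0.2)
    accel_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    accel_scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    initial_tilt: float = 0.0
    tilt_azimuth: float = 0.0
    quantize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.accel_bias = np.asarray(self.accel_bias, dtype=float)
        self.accel_scale = np.asarray(self.accel_scale, dtype=float)
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float)
        if self.accel_sigma < 0 or self.gyro_sigma < 0:
            raise ValueError("noise sigmas must be >= 0")

    @classmethod
    def randomized(cls, seed: int) -> "NoiseModel":
        """Draw a realistic sensor: |bias| <= 0.05 g, scale within 2% of
        unity, mounting tilt <= 10 deg, gyro bias <= 0.2 deg/s per axis."""
        rng = np.random.default_rng(seed)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        return cls(
            accel_bias=direction * rng.uniform(0.0, 0.05),
            accel_scale=rng.uniform(0.98, 1.02, size=3),
            gyro_bias=rng.uniform(-1.0, 1.0, size=3) * np.deg2rad(0.2),
            initial_tilt=rng.uniform(0.0, np.deg2rad(10.0)),
            tilt_azimuth=rng.uniform(0.0, 2.0 * np.pi),
            seed=seed,
        )

    @classmethod
    def noiseless(cls, quantize: bool = False) -> "NoiseModel":
        """A perfect sensor (for round-trip oracles)."""
        return cls(accel_sigma=0.0, gyro_sigma=0.0, quantize=quantize)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class KickTruth:
    """Analytic ground truth sampled on the sensor grid.

    World frame: +z up, +y the kick direction, origin at the foot's static
    start.  ``quat`` is the foot's sensor-to-world rotation (scalar first)
    *excluding* any mounting tilt, ``omega`` the spatial angular rate.
    ``onset_index`` is the first moving sample.
    """

    t: np.ndarray
    pos: np.ndarray
    vel: np.ndarray
    acc: np.ndarray
    quat: np.ndarray
    omega: np.ndarray
    dt: float
    onset_index: int

    def __len__(self) -> int:
        return len(self.t)


def _phase_c_geometry(dy: float, profile: KickProfile,
                      n_grid: int = 4001) -> float:
    """Arc length of the forward swing for displacement ``dy`` (geometry
    only; independent of its duration)."""
    h = profile.backswing_height
    h2 = profile.follow_through_height
    ax = profile.lateral_amplitude
    tau = np.linspace(0.0, 1.0, n_grid)
    dydtau = 2.0 * dy * np.sin(np.pi * tau) ** 2
    dzdtau = np.where(tau < 0.5,
                      -2.0 * h * _sp(np.clip(2.0 * tau, 0.0, 1.0)),
                      2.0 * h2 * _sp(np.clip(2.0 * tau - 1.0, 0.0, 1.0)))
    sv, spv = _s(tau), _sp(tau)
    dxdtau = 4.0 * ax * spv * (1.0 - 2.0 * sv)
    speed = np.sqrt(dydtau ** 2 + dzdtau ** 2 + dxdtau ** 2)
    return float(np.trapezoid(speed, tau))


def truth_trajectory(profile: KickProfile, dt: float) -> KickTruth:
    """Build the analytic kick and sample it at interval ``dt``.

    Raises :class:`ProfileError` when the commanded quantities are mutually
    infeasible (path shorter than the vertical motion requires, or
    ``kick_duration`` too short to fit the backswing once the forward-swing
    duration is fixed by the peak speed and path length).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = profile
    lead, tail = p.static_lead, p.static_tail

    if p.path_length_target == 0.0:  # degenerate: no motion at all
        n = lead + tail + max(1, round(p.kick_duration / dt))
        return KickTruth(
            t=np.arange(n) * dt, pos=np.zeros((n, 3)),
            vel=np.zeros((n, 3)), acc=np.zeros((n, 3)),
            quat=np.tile([1.0, 0, 0, 0], (n, 1)), omega=np.zeros((n, 3)),
            dt=dt, onset_index=lead)

    if p.peak_speed <= 0:
        raise ProfileError("peak_speed must be positive for a moving kick")
    h, h2 = p.backswing_height, p.follow_through_height
    if h2 >= h and h > 0:
        raise ProfileError(
            "follow_through_height must stay below the backswing apex")
    back_len = float(np.hypot(p.backswing_distance, h))
    target_c = p.path_length_target - back_len
    if target_c <= _phase_c_geometry(1e-9, p):
        raise ProfileError(
            "path_length_target too short for the commanded backswing and "
            "vertical motion")
    dy = brentq(lambda d: _phase_c_geometry(d, p) - target_c,
                1e-9, 10.0 * p.path_length_target, xtol=1e-10)

    # snap the forward swing to an even number of samples so the peak-speed
    # instant lands exactly on the grid, then re-derive the displacement
    nc = 2 * max(1, round(dy / p.peak_speed / dt))
    tc = nc * dt
    dy = 0.5 * p.peak_speed * tc
    nb = round((p.kick_duration - tc) / dt)
    tb = nb * dt
    if tb < 0.15:
        raise ProfileError(
            f"kick_duration {p.kick_duration} s leaves only {tb:.3f} s for "
            "the backswing; too short for the commanded peak speed and path")
    if back_len > 0 and 1.875 * back_len / tb >= 0.85 * p.peak_speed:
        raise ProfileError(
            "backswing would be faster than the forward swing; increase "
            "kick_duration or reduce backswing_distance")

    n = lead + nb + nc + tail
    t = np.arange(n) * dt
    pos = np.zeros((n, 3)); vel = np.zeros((n, 3)); acc = np.zeros((n, 3))
    phi = np.zeros(n); phidot = np.zeros(n)
    sweep = p.orientation_sweep

    # -- backswing: straight pull up-and-back on a shared quintic profile
    ib = slice(lead, lead + nb + 1)
    u = np.arange(nb + 1) / nb
    su, spu, sppu = _s(u), _sp(u), _spp(u)
    pos[ib, 1] = -p.backswing_distance * su
    pos[ib, 2] = h * su
    vel[ib, 1] = -p.backswing_distance * spu / tb
    vel[ib, 2] = h * spu / tb
    acc[ib, 1] = -p.backswing_distance * sppu / tb ** 2
    acc[ib, 2] = h * sppu / tb ** 2
    phi[ib] = -0.4 * sweep * su
    phidot[ib] = -0.4 * sweep * spu / tb

    # -- forward swing: sin^2 speed pulse forward, quintic dip-and-rise in z
    ic = slice(lead + nb, lead + nb + nc + 1)
    tau = np.arange(nc + 1) / nc
    pos[ic, 1] = -p.backswing_distance + p.peak_speed * tc * (
        tau / 2.0 - np.sin(2.0 * np.pi * tau) / (4.0 * np.pi))
    vel[ic, 1] = p.peak_speed * np.sin(np.pi * tau) ** 2
    acc[ic, 1] = p.peak_speed * np.pi * np.sin(2.0 * np.pi * tau) / tc
    first = tau < 0.5
    w1 = np.clip(2.0 * tau, 0.0, 1.0)
    w2 = np.clip(2.0 * tau - 1.0, 0.0, 1.0)
    pos[ic, 2] = np.where(first, h * (1.0 - _s(w1)), h2 * _s(w2))
    vel[ic, 2] = np.where(first, -2.0 * h * _sp(w1), 2.0 * h2 * _sp(w2)) / tc
    acc[ic, 2] = np.where(first, -4.0 * h * _spp(w1),
                          4.0 * h2 * _spp(w2)) / tc ** 2
    st, spt, sppt = _s(tau), _sp(tau), _spp(tau)
    axl = p.lateral_amplitude
    pos[ic, 0] = 4.0 * axl * st * (1.0 - st)
    vel[ic, 0] = 4.0 * axl * spt * (1.0 - 2.0 * st) / tc
    acc[ic, 0] = 4.0 * axl * (sppt * (1.0 - 2.0 * st)
                              - 2.0 * spt ** 2) / tc ** 2
    phi[ic] = sweep * (-0.4 + st)
    phidot[ic] = sweep * spt / tc

    # -- trailing rest at the follow-through point
    end = lead + nb + nc
    pos[end:] = pos[end]
    phi[end:] = phi[end]

    half = 0.5 * phi
    quat = np.column_stack([np.cos(half), np.sin(half),
                            np.zeros(n), np.zeros(n)])
    omega = np.column_stack([phidot, np.zeros(n), np.zeros(n)])
    return KickTruth(t=t, pos=pos, vel=vel, acc=acc, quat=quat, omega=omega,
                     dt=dt, onset_index=lead)


# ---------------------------------------------------------------------------
# inversion to raw IMU readings
# ---------------------------------------------------------------------------

@dataclass
class SimulatedImu:
    """A synthetic raw recording: SI stream plus (optionally) its counts."""

    stream: ImuStream
    accel_counts: np.ndarray | None
    gyro_counts: np.ndarray | None
    noise: NoiseModel
    tilt_quat: np.ndarray

    def raw_samples(self) -> Iterator[RawImuSample]:
        if self.accel_counts is None:
            raise ValueError("stream was generated without quantization")
        for i, (a, g) in enumerate(zip(self.accel_counts, self.gyro_counts)):
            yield RawImuSample(index=i, accel_counts=tuple(int(v) for v in a),
                              gyro_counts=tuple(int(v) for v in g))

    def write(self, path, config: PipelineConfig) -> None:
        """Write in the text dialect ``read_stream`` ingests: unsigned
        16-bit words when quantized, full-precision SI otherwise."""
        if self.accel_counts is not None:
            words = encode_counts(
                np.hstack([self.accel_counts, self.gyro_counts]))
            np.savetxt(path, words, fmt="%d", header="ax ay az gx gy gz")
        else:
            from .io import write_stream
            write_stream(path, self.stream, config, units="si")


def imu_from_truth(truth: KickTruth, noise: NoiseModel,
                   config: PipelineConfig) -> SimulatedImu:
    """Invert a ground-truth kick into the sensor's raw measurements.

    Applies, in order: the mounting tilt and per-sample foot rotation (so
    gravity appears in the sensor frame), the accelerometer deviation model
    ``measured = L (true + b)``, additive Gaussian noise, and 16-bit
    quantization at the configured full-scale ranges (optional).  Warns when
    the specific force would clip at full scale.
    """
    if abs(truth.dt - config.dt) > 1e-12:
        raise ValueError("truth must be sampled at the configured rate")
    rng = np.random.default_rng(
        np.random.SeedSequence(noise.seed, spawn_key=(1,)))

    tilt_axis = np.array([np.cos(noise.tilt_azimuth),
                          np.sin(noise.tilt_azimuth), 0.0])
    q_tilt = quat_from_axis_angle(tilt_axis, noise.initial_tilt)
    q_ws = quat_multiply(truth.quat, q_tilt)      # sensor -> world
    q_sw = quat_conjugate(q_ws)                   # world -> sensor

    f_world = truth.acc + np.array([0.0, 0.0, G_STD])
    f_sensor = rotate_by_quaternion(q_sw, f_world)
    omega_sensor = rotate_by_quaternion(q_sw, truth.omega)

    accel_g = noise.accel_scale * (f_sensor / G_STD + noise.accel_bias)
    accel_g = accel_g + rng.normal(0.0, 1.0, f_sensor.shape) \
        * (noise.accel_sigma / G_STD)
    gyro = omega_sensor + noise.gyro_bias \
        + rng.normal(0.0, 1.0, omega_sensor.shape) * noise.gyro_sigma

    if not noise.quantize:
        stream = ImuStream(accel=accel_g * G_STD, gyro=gyro, dt=config.dt)
        return SimulatedImu(stream=stream, accel_counts=None,
                            gyro_counts=None, noise=noise, tilt_quat=q_tilt)

    a_counts = np.round(accel_g * G_STD / accel_lsb(config))
    g_counts = np.round(gyro / gyro_lsb(config))
    if np.any(np.abs(a_counts) > _COUNT_HALF - 1) or \
            np.any(np.abs(g_counts) > _COUNT_HALF - 1):
        warnings.warn("specific force or rate exceeds the configured full "
                      "scale; clipping", stacklevel=2)
    a_counts = np.clip(a_counts, -_COUNT_HALF, _COUNT_HALF - 1).astype(int)
    g_counts = np.clip(g_counts, -_COUNT_HALF, _COUNT_HALF - 1).astype(int)
    accel_si = a_counts * accel_lsb(config)
    gyro_si = g_counts * gyro_lsb(config)
    stream = ImuStream(accel=accel_si, gyro=gyro_si, dt=config.dt)
    return SimulatedImu(stream=stream, accel_counts=a_counts,
                        gyro_counts=g_counts, noise=noise, tilt_quat=q_tilt)


def make_calibration_set(noise: NoiseModel, n_orientations: int = 24,
                         samples_per_orientation: int = 25) -> np.ndarray:
    """Static gravity readings at quasi-uniform orientations, g units.

    Unit gravity vectors on a Fibonacci sphere are pushed through the same
    deviation model and noise as the kick stream; feeding the result to
    :func:`kicktrack.calibration.fit_sphere` closes the calibration loop.
    """
    if n_orientations < 6:
        raise ValueError("need at least 6 orientations")
    rng = np.random.default_rng(
        np.random.SeedSequence(noise.seed, spawn_key=(2,)))
    k = np.arange(n_orientations)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = 1.0 - 2.0 * (k + 0.5) / n_orientations
    r = np.sqrt(1.0 - z ** 2)
    dirs = np.column_stack([r * np.cos(golden * k),
                            r * np.sin(golden * k), z])
    g_true = np.repeat(dirs, samples_per_orientation, axis=0)
    measured = noise.accel_scale * (g_true + noise.accel_bias)
    measured = measured + rng.normal(0.0, 1.0, measured.shape) \
        * (noise.accel_sigma / G_STD)
    return measured


def simulate_kick(profile: KickProfile | None = None,
                  noise: NoiseModel | None = None,
                  config: PipelineConfig | None = None
                  ) -> tuple[KickTruth, SimulatedImu]:
    """Generate one kick: analytic truth plus its raw IMU recording."""
    profile = profile or KickProfile()
    noise = noise or NoiseModel()
    config = config or PipelineConfig()
    truth = truth_trajectory(profile, config.dt)
    return truth, imu_from_truth(truth, noise, config)


# ---------------------------------------------------------------------------
# closed-loop experiment (simulate -> calibrate -> reconstruct -> score)
# ---------------------------------------------------------------------------

def synthetic_kick_experiment(seed: int,
                              profile: KickProfile | None = None,
                              config: PipelineConfig | None = None,
                              noise: NoiseModel | None = None,
                              return_objects: bool = False) -> dict:
    """Run the full closed loop for one seeded kick and score it.

    Simulates a kick under :meth:`NoiseModel.randomized`, fits the
    accelerometer calibration from a simulated multi-orientation static set,
    reconstructs the trajectory from the raw stream, and compares against
    the analytic truth over the motion span (onset to end of record).

    Returns a dict with ``position_rmse`` (m, 3D), ``velocity_rmse`` (m/s,
    along each track's own kick direction), ``max_speed_error_pct`` and
    ``backswing_height_error_pct`` (relative to the commanded values), plus
    the extracted :class:`~kicktrack.metrics.KickMetrics` and sample counts.
    """
    profile = profile or KickProfile()
    config = config or PipelineConfig()
    noise = noise or NoiseModel.randomized(seed)

    truth, sim = simulate_kick(profile, noise, config)
    model = fit_sphere(make_calibration_set(noise))
    track = reconstruct(sim.stream, model, config)

    span = slice(truth.onset_index, len(track))
    diff = track.pos[span] - truth.pos[span]
    position_rmse = float(np.sqrt(np.mean(np.sum(diff ** 2, axis=1))))
    d_rec = kick_direction(track.pos[span])
    d_true = kick_direction(truth.pos[span])
    vdiff = track.vel[span] @ d_rec - truth.vel[span] @ d_true
    velocity_rmse = float(np.sqrt(np.mean(vdiff ** 2)))

    met = extract_metrics(track)
    result = {
        "position_rmse": position_rmse,
        "velocity_rmse": velocity_rmse,
        "max_speed_error_pct": 100.0 * abs(met.max_speed - profile.peak_speed)
        / profile.peak_speed,
        "backswing_height_error_pct": 100.0
        * abs(met.backswing_height - profile.backswing_height)
        / profile.backswing_height,
        "metrics": met,
        "n_samples": len(track),
        "n_motion_samples": len(track) - truth.onset_index,
    }
    if return_objects:
        result.update(truth=truth, sim=sim, track=track, model=model)
    return result
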