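"""Strapdown dead reckoning: gravity removal, leveling and gated integration.

After the accelerations are rotated into the initial (static) sensor frame,
the remaining steps to a world-frame trajectory are:

1. *Gravity compensation* — the mean specific force over the leading static
   window (default 500 samples) is the gravity vector seen by the sensor at
   rest; subtracting it from every sample leaves only motion acceleration.
2. *Tilt correction* — the same static mean tells us how the initial frame
   is tilted relative to the world: roll and pitch are recovered from the
   gravity components (yaw is unobservable without a magnetometer and fixed
   at zero) and the combined rotation Rz Ry Rx levels the frame so that +z
   points opposite gravity.
3. *Acceleration gating* — samples whose norm falls below a threshold
   (default 0.392 m/s^2) are zeroed: vibration, wind and imperfect gravity
   compensation otherwise accumulate into large drift through the double
   integration.
4. *Trapezoidal double integration with zero-velocity updates* — velocity
   integrates as v_i = v_{i-1} + (a_i + a_{i-1})/2 * dt (and position by the
   same averaged rule on velocity).  Whenever 15 consecutive gated
   accelerations are exactly zero the sensor is declared static and the
   velocity is reset to zero, arresting the constant-velocity drift that
   pure integration would otherwise carry out of every movement.

World frame: +z up (opposite gravity), origin at the static starting
position of the foot.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .attitude import transform_stream
from .calibration import CalibrationModel, calibrate_stream
from .io import (G_STD, DegenerateAttitudeError, ImuStream, KickTrackError,
                 PipelineConfig)


# ---------------------------------------------------------------------------
# static offset and leveling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StaticOffset:
    """Mean specific force over the static window, initial coordinates.

    For a valid static capture the norm should sit within ~5% of 1 g; a
    larger discrepancy usually means the lead-in was not actually still.
    """

    offset_accl: np.ndarray

    @property
    def norm(self) -> float:
        return float(np.linalg.norm(self.offset_accl))


def estimate_static_offset(accels: np.ndarray, window: int) -> StaticOffset:
    """Component-wise mean of the first ``window`` samples."""
    accels = np.asarray(accels, dtype=float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(accels) < window:
        raise KickTrackError(
            f"stream has {len(accels)} samples, shorter than the "
            f"{window}-sample static window")
    offset = StaticOffset(offset_accl=accels[:window].mean(axis=0))
    if abs(offset.norm - G_STD) > 0.05 * G_STD:
        warnings.warn(
            f"static-window mean acceleration norm {offset.norm:.3f} m/s^2 "
            "deviates more than 5% from 1 g; the lead-in may not be static",
            stacklevel=2)
    return offset


def compensate_gravity(accels: np.ndarray,
                       offset: StaticOffset) -> np.ndarray:
    """Subtract the static gravity offset from every sample."""
    return np.asarray(accels, dtype=float) - offset.offset_accl


@dataclass(frozen=True)
class TiltCorrection:
    """Roll/pitch leveling of the initial frame; yaw fixed at zero.

    ``trotate`` is the orthogonal matrix Rz(yaw) Ry(pitch) Rx(roll) that
    maps initial-frame vectors to the leveled world frame.
    """

    roll: float
    pitch: float
    yaw: float
    trotate: np.ndarray


def tilt_correction(offset: StaticOffset,
                    exact: bool = True) -> TiltCorrection:
    """Build the leveling rotation from the static gravity direction.

    ``roll = arctan(offset_y / offset_z)`` always; for the pitch two variants
    are available:

    * ``exact=True`` (default): ``pitch = -arctan(offset_x /
      hypot(offset_y, offset_z))``, which aligns the rotated offset with +z
      to machine precision for any tilt;
    * ``exact=False``: the small-angle form ``pitch = -arctan(offset_x /
      offset_z)``, identical to first order and adequate below ~15 deg, left
      available for comparison.

    Raises :class:`DegenerateAttitudeError` when the z component of the
    offset vanishes (sensor lying on its side; roll/pitch undefined).
    """
    ox, oy, oz = offset.offset_accl
    if abs(oz) < 1e-3 * max(offset.norm, 1e-30):
        raise DegenerateAttitudeError(
            "static gravity has no z component; roll/pitch leveling is "
            "degenerate (sensor on its side?)")
    roll = np.arctan2(oy, oz)
    if exact:
        pitch = -np.arctan2(ox, np.hypot(oy, oz))
    else:
        pitch = -np.arctan(ox / oz)
    yaw = 0.0

    cr, sr = np.cos(roll), np.sin(roll)
    cp, sp = np.cos(pitch), np.sin(pitch)
    cy, sy = np.cos(yaw), np.sin(yaw)
    rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
    ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
    rz = np.array([[cy, -sy, 0], [sy, cy, 0], [0, 0, 1]])
    return TiltCorrection(roll=float(roll), pitch=float(pitch), yaw=yaw,
                          trotate=rz @ ry @ rx)


def apply_tilt(accels: np.ndarray, tilt: TiltCorrection) -> np.ndarray:
    """Left-multiply every sample by the leveling rotation."""
    return np.asarray(accels, dtype=float) @ tilt.trotate.T


# ---------------------------------------------------------------------------
# gating and integration
# ---------------------------------------------------------------------------

def gate_acceleration(accels: np.ndarray, gate: float) -> np.ndarray:
    """Zero samples whose Euclidean norm is below the gate (m/s^2).

    Applied to the vector norm rather than per axis so that gating never
    distorts the direction of retained samples; it can only zero them.
    """
    accels = np.asarray(accels, dtype=float).copy()
    accels[np.linalg.norm(accels, axis=1) < gate] = 0.0
    return accels


@dataclass
class KinematicTrack:
    """Per-sample world-frame kinematics of the foot.

    ``accel`` is the gated, gravity-free world-frame acceleration (m/s^2),
    ``vel`` and ``pos`` its first and second trapezoidal integrals, and
    ``stationary`` flags the samples where the zero-velocity detector held
    the foot still.  ``pos[0]`` is the origin and ``vel[0]`` zero by
    construction.
    """

    accel: np.ndarray
    vel: np.ndarray
    pos: np.ndarray
    stationary: np.ndarray
    dt: float

    def __len__(self) -> int:
        return len(self.pos)

    @property
    def t(self) -> np.ndarray:
        return np.arange(len(self)) * self.dt

    @property
    def speed(self) -> np.ndarray:
        """Per-sample velocity norm, m/s."""
        return np.linalg.norm(self.vel, axis=1)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({
            "index": np.arange(len(self)), "t": self.t,
            "ax": self.accel[:, 0], "ay": self.accel[:, 1],
            "az": self.accel[:, 2],
            "vx": self.vel[:, 0], "vy": self.vel[:, 1], "vz": self.vel[:, 2],
            "px": self.pos[:, 0], "py": self.pos[:, 1], "pz": self.pos[:, 2],
            "stationary": self.stationary.astype(int),
        })

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "KinematicTrack":
        import pandas as pd

        df = pd.read_csv(path)
        t = df["t"].to_numpy(float)
        dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
        return cls(
            accel=df[["ax", "ay", "az"]].to_numpy(float),
            vel=df[["vx", "vy", "vz"]].to_numpy(float),
            pos=df[["px", "py", "pz"]].to_numpy(float),
            stationary=df["stationary"].to_numpy(bool),
            dt=dt,
        )


def integrate_track(accels: np.ndarray,
                    config: PipelineConfig) -> KinematicTrack:
    """Double-integrate gated accelerations with zero-velocity updates.

    Velocity uses the averaged-sample (trapezoidal) rule
    ``v_i = v_{i-1} + (a_i + a_{i-1})/2 * dt`` — exact for piecewise-linear
    acceleration — and position applies the same rule to velocity.  After
    each velocity step, if the trailing ``zupt_run_length`` gated
    accelerations are all zero the sensor is declared static: the sample is
    flagged and the velocity reset to zero for as long as the zero run
    persists.  (Any residual velocity is below or above ``vel_gate`` alike;
    the reset clamps both, so the 0.196 m/s threshold is subsumed by the
    detector in this causal formulation.)  The first sample has no
    predecessor, so v_0 = 0 and p_0 is the origin.
    """
    a = np.asarray(accels, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("accels must be (n, 3)")
    n = len(a)
    dt = config.dt
    vel = np.zeros((n, 3))
    pos = np.zeros((n, 3))
    stationary = np.zeros(n, dtype=bool)
    if n == 0:
        return KinematicTrack(a, vel, pos, stationary, dt)

    is_zero = ~a.any(axis=1)
    run = 1 if is_zero[0] else 0
    in_static = run >= config.zupt_run_length
    stationary[0] = in_static or is_zero[0]
    for i in range(1, n):
        v = vel[i - 1] + 0.5 * (a[i] + a[i - 1]) * dt
        if is_zero[i]:
            run += 1
        else:
            run = 0
            in_static = False
        if run >= config.zupt_run_length:
            in_static = True
        if in_static:
            v = np.zeros(3)  # ZUPT: clamp residual velocity (incl. < vel_gate)
            stationary[i] = True
        vel[i] = v
        pos[i] = pos[i - 1] + 0.5 * (vel[i] + vel[i - 1]) * dt
    return KinematicTrack(accel=a, vel=vel, pos=pos, stationary=stationary,
                          dt=dt)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def reconstruct(stream: ImuStream,
                model: CalibrationModel | None = None,
                config: PipelineConfig | None = None,
                return_details: bool = False):
    """Run the full chain from a raw SI stream to a kinematic track.

    calibrate -> attitude/rotate -> static offset -> gravity compensation ->
    tilt leveling -> gate -> integrate.  The stream must begin with at least
    ``config.static_window`` stationary samples.

    Parameters
    ----------
    stream:
        Six-axis stream in SI units (see :func:`kicktrack.io.read_stream`).
    model:
        Accelerometer calibration model; identity if omitted (the stream
        normalisation and gyro-bias subtraction still apply).
    return_details:
        Also return a dict with the intermediate products (attitude
        quaternions, static offset, tilt, fitted model).
    """
    config = config or PipelineConfig()
    model = model or CalibrationModel.identity()

    cal_stream, fitted = calibrate_stream(stream, model, config)
    accel_initial, quats = transform_stream(cal_stream)
    offset = estimate_static_offset(accel_initial, config.static_window)
    accel_free = compensate_gravity(accel_initial, offset)
    tilt = tilt_correction(offset)
    accel_world = apply_tilt(accel_free, tilt)
    gated = gate_acceleration(accel_world, config.accel_gate)
    track = integrate_track(gated, config)
    if return_details:
        return track, {
            "quats": quats, "offset": offset, "tilt": tilt, "model": fitted,
        }
    return track
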