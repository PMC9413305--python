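"""Kick-quality metrics and agreement analysis against a reference track.

The quantities a coach cares about in an instep kick: the total path swept by
the foot, the maximum foot speed (and where on the trajectory it occurs —
ideally at the bottom of the swing, near ball contact) and the backswing apex
height (how high the foot is pulled up before the forward swing, a proxy for
kick power).  For validation against a reference trajectory — a camera system
or the simulator's analytic truth — the module resamples the IMU track onto
the reference timestamps, computes position/velocity RMSEs and runs a
Bland–Altman limits-of-agreement analysis per axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import AlignmentError, KickTrackError, PhaseDetectionError
from .reconstruction import KinematicTrack


# ---------------------------------------------------------------------------
# kick metrics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KickMetrics:
    """Summary metrics of a reconstructed kick."""

    path_length: float            # m
    max_speed: float              # m/s
    max_speed_index: int
    max_speed_position: np.ndarray  # m, world frame
    backswing_height: float       # m, relative to the starting height
    backswing_apex_index: int

    def to_dict(self) -> dict:
        return {
            "path_length_m": self.path_length,
            "max_speed_mps": self.max_speed,
            "max_speed_index": int(self.max_speed_index),
            "max_speed_position_m": [float(v)
                                     for v in self.max_speed_position],
            "backswing_height_m": self.backswing_height,
            "backswing_apex_index": int(self.backswing_apex_index),
        }


def _positions(track) -> np.ndarray:
    pos = getattr(track, "pos", track)
    return np.asarray(pos, dtype=float)


def path_length(track) -> float:
    """Sum of Euclidean distances between consecutive positions, m.

    Accepts a :class:`KinematicTrack` or a bare (n, 3) position array.  Always
    at least the straight-line start-to-end distance, and invariant under
    rigid rotation of the track.
    """
    pos = _positions(track)
    if len(pos) < 2:
        raise KickTrackError("path length needs at least 2 samples")
    return float(np.sum(np.linalg.norm(np.diff(pos, axis=0), axis=1)))


def max_speed(track: KinematicTrack) -> tuple[float, int, np.ndarray]:
    """Maximum of the per-sample speed, with its index and position.

    Ties resolve to the earliest index.
    """
    if len(track) == 0:
        raise KickTrackError("empty track")
    speeds = track.speed
    idx = int(np.argmax(speeds))
    return float(speeds[idx]), idx, track.pos[idx].copy()


def backswing_height(track: KinematicTrack) -> tuple[float, int]:
    """Apex height of the pull-back phase, m above the starting height.

    The backswing apex is the maximum vertical (z) position over the samples
    *before* the maximum-speed instant, measured relative to the starting z.
    Raises :class:`PhaseDetectionError` when no sample precedes the speed
    peak (no backswing phase to inspect).
    """
    _, peak_idx, _ = max_speed(track)
    if peak_idx == 0:
        raise PhaseDetectionError(
            "maximum speed occurs at the first sample; no backswing phase "
            "precedes it")
    z = track.pos[:peak_idx, 2] - track.pos[0, 2]
    apex_idx = int(np.argmax(z))
    return float(z[apex_idx]), apex_idx


def extract_metrics(track: KinematicTrack) -> KickMetrics:
    """All kick metrics of a track; degenerate (motionless) tracks give zeros."""
    pl = path_length(track)
    speed, idx, pos = max_speed(track)
    if speed == 0.0:  # static stream: no kick to characterise
        return KickMetrics(path_length=pl, max_speed=0.0, max_speed_index=0,
                           max_speed_position=pos, backswing_height=0.0,
                           backswing_apex_index=0)
    height, apex_idx = backswing_height(track)
    return KickMetrics(path_length=pl, max_speed=speed, max_speed_index=idx,
                       max_speed_position=pos, backswing_height=height,
                       backswing_apex_index=apex_idx)


# ---------------------------------------------------------------------------
# pairing against a reference trajectory
# ---------------------------------------------------------------------------

def motion_onset(t: np.ndarray, pos: np.ndarray,
                 threshold: float = 0.05, sustain: int = 3) -> float:
    """Time of the first sustained movement in a position sequence.

    Onset is the first sample whose finite-difference speed exceeds
    ``threshold`` (m/s) for ``sustain`` consecutive samples.
    """
    t = np.asarray(t, dtype=float)
    pos = np.asarray(pos, dtype=float)
    if len(t) < sustain + 1:
        raise AlignmentError("sequence too short for onset detection")
    speed = np.linalg.norm(np.gradient(pos, t, axis=0), axis=1)
    above = speed > threshold
    for i in range(len(above) - sustain + 1):
        if above[i:i + sustain].all():
            return float(t[i])
    raise AlignmentError("no sustained motion found in sequence")


def resample_to_reference(track_t: np.ndarray, track_pos: np.ndarray,
                          ref_t: np.ndarray, ref_pos: np.ndarray,
                          align: str = "clock"
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pair an IMU track with a reference sampled at a different rate.

    The IMU positions are linearly interpolated at the reference timestamps
    and the pairs truncated to the overlapping span.  ``align="clock"``
    assumes the two sequences share a timebase (the simulator's truth does);
    ``align="onset"`` first shifts the reference so that both motion onsets
    coincide, for references (e.g. camera exports) that start at the
    beginning of the motion.

    Returns ``(imu_at_ref, ref_used, t_used)``.
    """
    track_t = np.asarray(track_t, dtype=float)
    track_pos = np.asarray(track_pos, dtype=float)
    ref_t = np.asarray(ref_t, dtype=float)
    ref_pos = np.asarray(ref_pos, dtype=float)
    if align == "onset":
        shift = motion_onset(track_t, track_pos) - motion_onset(ref_t,
                                                                ref_pos)
        ref_t = ref_t + shift
    elif align != "clock":
        raise ValueError("align must be 'clock' or 'onset'")
    mask = (ref_t >= track_t[0]) & (ref_t <= track_t[-1])
    if not mask.any():
        raise AlignmentError("trajectories have no overlapping time span")
    t_used = ref_t[mask]
    imu_at_ref = np.column_stack(
        [np.interp(t_used, track_t, track_pos[:, k]) for k in range(3)])
    return imu_at_ref, ref_pos[mask], t_used


def trajectory_rmse(pos_a: np.ndarray, pos_b: np.ndarray,
                    vel_a: np.ndarray | None = None,
                    vel_b: np.ndarray | None = None,
                    t: np.ndarray | None = None,
                    direction: np.ndarray | None = None
                    ) -> tuple[float, float]:
    """Position and velocity RMSE between paired trajectories.

    Position RMSE is the root mean square of the 3D point-to-point distances.
    Velocity RMSE applies the same formula to paired velocities — supplied
    directly, or finite-differenced from the positions when ``t`` is given.
    With ``direction`` (a unit 3-vector), velocities are first projected onto
    it and the RMSE taken over the scalar differences (the "along the kick"
    variant).
    """
    pos_a = np.asarray(pos_a, dtype=float)
    pos_b = np.asarray(pos_b, dtype=float)
    if len(pos_a) != len(pos_b) or len(pos_a) == 0:
        raise KickTrackError("need equal-length, non-empty pairings")
    pos_rmse = float(np.sqrt(np.mean(
        np.sum((pos_a - pos_b) ** 2, axis=1))))

    if vel_a is None or vel_b is None:
        if t is None:
            return pos_rmse, float("nan")
        vel_a = np.gradient(pos_a, t, axis=0)
        vel_b = np.gradient(pos_b, t, axis=0)
    vel_a = np.asarray(vel_a, dtype=float)
    vel_b = np.asarray(vel_b, dtype=float)
    if direction is not None:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        diff = vel_a @ d - vel_b @ d
        vel_rmse = float(np.sqrt(np.mean(diff ** 2)))
    else:
        vel_rmse = float(np.sqrt(np.mean(
            np.sum((vel_a - vel_b) ** 2, axis=1))))
    return pos_rmse, vel_rmse


def kick_direction(pos: np.ndarray) -> np.ndarray:
    """Horizontal unit vector of the net displacement (the kick direction)."""
    pos = np.asarray(pos, dtype=float)
    d = pos[-1] - pos[0]
    d[2] = 0.0
    n = np.linalg.norm(d)
    if n == 0:
        raise KickTrackError("no horizontal displacement; kick direction "
                             "undefined")
    return d / n


# ---------------------------------------------------------------------------
# Bland–Altman agreement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlandAltmanAxis:
    """Limits-of-agreement statistics for one axis."""

    bias: float                # mean difference
    loa_low: float             # bias - 1.96 SD
    loa_high: float            # bias + 1.96 SD
    n_outside: int
    n: int

    @property
    def fraction_outside(self) -> float:
        return self.n_outside / self.n if self.n else 0.0


def bland_altman(a: np.ndarray, b: np.ndarray) -> list[BlandAltmanAxis]:
    """Per-axis Bland–Altman analysis of two paired measurement methods.

    For each axis the differences d = a - b give the bias (mean of d) and the
    95% limits of agreement bias +/- 1.96 SD(d); the count of points outside
    the limits quantifies disagreement.  Zero-variance axes collapse the
    limits onto the bias (reported, not an error).  Accepts (n,) or (n, k)
    arrays; needs at least 3 pairs.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(b, dtype=float).T).T
    if a.shape != b.shape or a.shape[0] < 3:
        raise KickTrackError("Bland–Altman needs >= 3 equal-length pairs")
    out = []
    for k in range(a.shape[1]):
        d = a[:, k] - b[:, k]
        bias = float(np.mean(d))
        sd = float(np.std(d, ddof=1))
        low, high = bias - 1.96 * sd, bias + 1.96 * sd
        n_out = int(np.sum((d < low) | (d > high)))
        out.append(BlandAltmanAxis(bias=bias, loa_low=low, loa_high=high,
                                   n_outside=n_out, n=len(d)))
    return out


@dataclass(frozen=True)
class AgreementReport:
    """End-to-end agreement of a reconstructed track with a reference."""

    position_rmse: float        # m, 3D
    velocity_rmse: float        # m/s, along the kick direction
    axes: Sequence[BlandAltmanAxis]
    n_pairs: int                # pooled over axes

    @property
    def n_outside(self) -> int:
        return sum(ax.n_outside for ax in self.axes)

    @property
    def fraction_outside(self) -> float:
        return self.n_outside / self.n_pairs if self.n_pairs else 0.0

    def to_dict(self) -> dict:
        return {
            "position_rmse_m": self.position_rmse,
            "velocity_rmse_mps": self.velocity_rmse,
            "n_pairs": self.n_pairs,
            "n_outside_limits": self.n_outside,
            "fraction_outside_limits": self.fraction_outside,
            "axes": [{
                "bias": ax.bias, "loa_low": ax.loa_low,
                "loa_high": ax.loa_high, "n_outside": ax.n_outside,
            } for ax in self.axes],
        }


def evaluate_against_reference(track: KinematicTrack, ref_t: np.ndarray,
                               ref_pos: np.ndarray,
                               ref_vel: np.ndarray | None = None,
                               align: str = "clock") -> AgreementReport:
    """Resample, compute RMSEs and Bland–Altman stats in one call.

    Velocity RMSE is taken along each trajectory's own kick direction (the
    horizontal unit vector of its net displacement), comparing the along-kick
    speed profiles; reference velocities are finite-differenced when not
    supplied.
    """
    imu_pos, ref_used, t_used = resample_to_reference(
        track.t, track.pos, ref_t, ref_pos, align=align)
    imu_vel = np.column_stack(
        [np.interp(t_used, track.t, track.vel[:, k]) for k in range(3)])
    if ref_vel is None:
        ref_v = np.gradient(ref_used, t_used, axis=0)
    else:
        mask = (np.asarray(ref_t) >= track.t[0]) & \
               (np.asarray(ref_t) <= track.t[-1])
        ref_v = np.asarray(ref_vel, dtype=float)[mask]

    d_imu = kick_direction(imu_pos)
    d_ref = kick_direction(ref_used)
    diff = imu_vel @ d_imu - ref_v @ d_ref
    vel_rmse = float(np.sqrt(np.mean(diff ** 2)))
    pos_rmse, _ = trajectory_rmse(imu_pos, ref_used)
    axes = bland_altman(imu_pos, ref_used)
    return AgreementReport(position_rmse=pos_rmse, velocity_rmse=vel_rmse,
                           axes=axes, n_pairs=3 * len(imu_pos))
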