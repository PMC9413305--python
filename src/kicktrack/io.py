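"""Raw IMU stream decoding, unit scaling, file I/O and pipeline configuration.

The sensor emulated throughout the package is a wide-range six-axis MEMS IMU
(three-axis accelerometer + three-axis gyroscope) strapped to the instep of
the kicking foot and sampled at a fixed rate (100 Hz by default).  Each axis
is digitised by a 16-bit ADC: raw words are unsigned 16-bit integers whose
upper half encodes negative readings in two's complement.  Full-scale ranges
default to +/-30 g for the accelerometer and +/-4000 deg/s for the gyroscope —
wide enough for the ~12 g peaks of a hard instep kick.

All downstream maths is done in SI units (m/s^2, rad/s); conversion from
counts or degree-based files happens once, at ingest.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import yaml

#: standard gravity, m/s^2 — the single constant used everywhere a "g" appears
G_STD = 9.80665

_COUNT_HALF = 32768  # 2^15; full scale maps to this many LSB


# ---------------------------------------------------------------------------
# errors
# ---------------------------------------------------------------------------

class KickTrackError(Exception):
    """Base class for all errors raised by this package."""


class StreamParseError(KickTrackError):
    """A raw IMU text stream could not be parsed."""


class DegenerateGeometryError(KickTrackError):
    """Calibration geometry is rank-deficient (e.g. coplanar orientations)."""


class DegenerateAttitudeError(KickTrackError):
    """Static gravity vector unusable for leveling (sensor on its side)."""


class ProfileError(KickTrackError):
    """A synthetic kick profile is internally infeasible."""


class AlignmentError(KickTrackError):
    """Two trajectories share no overlapping time span."""


class PhaseDetectionError(KickTrackError):
    """A required motion phase (e.g. backswing) is absent from a track."""


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Tunable parameters of the reconstruction pipeline.

    Defaults reproduce the reference operating point of the system: a 100 Hz
    six-axis stream at +/-30 g and +/-4000 deg/s, a 500-sample (5 s) static
    lead-in used for gravity/bias estimation, an acceleration gate of
    0.392 m/s^2 (0.04 g), a residual-velocity threshold of 0.196 m/s and a
    15-sample stationarity rule for zero-velocity updates.

    Attributes
    ----------
    sample_rate_hz:
        Sampling rate of the stream, Hz.
    accel_full_scale_g:
        Accelerometer full-scale range, g (one-sided).
    gyro_full_scale_dps:
        Gyroscope full-scale range, deg/s (one-sided).
    static_window:
        Number of leading samples assumed stationary; used for the gravity
        offset, the calibration norm rescale and the gyro-bias estimate.
    accel_gate:
        Acceleration norms below this (m/s^2) are zeroed before integration.
    vel_gate:
        Residual-velocity threshold (m/s) clamped inside detected static runs.
    zupt_run_length:
        Consecutive gated-zero samples required to declare a static state.
    gyro_in_degrees:
        Unit of gyroscope columns in *physical-unit* text files (counts files
        are always scaled through the full-scale range).
    subtract_gyro_bias:
        Estimate the gyro bias as the static-window mean rate and subtract it
        (strongly recommended: uncorrected bias dominates attitude drift).
    """

    sample_rate_hz: float = 100.0
    accel_full_scale_g: float = 30.0
    gyro_full_scale_dps: float = 4000.0
    static_window: int = 500
    accel_gate: float = 0.392
    vel_gate: float = 0.196
    zupt_run_length: int = 15
    gyro_in_degrees: bool = True
    subtract_gyro_bias: bool = True

    def __post_init__(self) -> None:
        for name in ("sample_rate_hz", "accel_full_scale_g",
                     "gyro_full_scale_dps", "static_window", "accel_gate",
                     "vel_gate", "zupt_run_length"):
            if getattr(self, name) < 0 or (
                    name not in ("accel_gate", "vel_gate")
                    and getattr(self, name) <= 0):
                raise ValueError(f"{name} must be positive")
        if self.static_window < self.zupt_run_length:
            raise ValueError("static_window must be >= zupt_run_length")

    @property
    def dt(self) -> float:
        """Sampling interval, s."""
        return 1.0 / self.sample_rate_hz

    # -- persistence ---------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Load a config from a YAML mapping of field names to values."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise StreamParseError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StreamParseError(
                f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh,
                           default_flow_style=False, sort_keys=False)


# ---------------------------------------------------------------------------
# sample containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RawImuSample:
    """One six-axis reading in signed sensor counts (LSB)."""

    index: int
    accel_counts: tuple[int, int, int]
    gyro_counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        for c in (*self.accel_counts, *self.gyro_counts):
            if not (-_COUNT_HALF <= c <= _COUNT_HALF - 1):
                raise ValueError(f"count {c} outside signed 16-bit range")


@dataclass(frozen=True)
class ImuRecord:
    """One six-axis reading in physical units (sensor frame).

    ``accel`` in m/s^2, ``gyro`` in rad/s, ``dt`` the sampling interval in s.
    """

    accel: np.ndarray
    gyro: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (np.all(np.isfinite(self.accel))
                and np.all(np.isfinite(self.gyro))):
            raise ValueError("non-finite IMU components")


@dataclass
class ImuStream:
    """A uniformly sampled six-axis stream in SI units.

    ``accel``: (n, 3) specific force in the sensor frame, m/s^2.
    ``gyro``:  (n, 3) angular rate in the sensor frame, rad/s.
    ``dt``:    sampling interval, s.
    """

    accel: np.ndarray
    gyro: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.accel = np.atleast_2d(np.asarray(self.accel, dtype=float))
        self.gyro = np.atleast_2d(np.asarray(self.gyro, dtype=float))
        if self.accel.shape != self.gyro.shape or self.accel.shape[1] != 3:
            raise ValueError("accel and gyro must both be (n, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    def __len__(self) -> int:
        return self.accel.shape[0]

    @property
    def t(self) -> np.ndarray:
        """Sample times, s, starting at 0."""
        return np.arange(len(self)) * self.dt

    def records(self) -> Iterator[ImuRecord]:
        for a, g in zip(self.accel, self.gyro):
            yield ImuRecord(accel=a, gyro=g, dt=self.dt)


# ---------------------------------------------------------------------------
# count decoding and scaling
# ---------------------------------------------------------------------------

def decode_counts(word):
    """Interpret an unsigned 16-bit ADC word as a signed integer.

    Words >= 2^15 encode negative values in two's complement.  Accepts a
    scalar or an array; the mapping is a bijection between [0, 65535] and
    [-32768, 32767].
    """
    arr = np.asarray(word)
    if np.any(arr < 0) or np.any(arr > 2 * _COUNT_HALF - 1):
        raise ValueError("word outside unsigned 16-bit range [0, 65535]")
    out = np.where(arr >= _COUNT_HALF, arr - 2 * _COUNT_HALF, arr)
    if np.isscalar(word) or np.ndim(word) == 0:
        return int(out)
    return out.astype(np.int64)


def encode_counts(value):
    """Inverse of :func:`decode_counts`: signed integer to unsigned word."""
    arr = np.asarray(value)
    if np.any(arr < -_COUNT_HALF) or np.any(arr > _COUNT_HALF - 1):
        raise ValueError("value outside signed 16-bit range")
    out = np.where(arr < 0, arr + 2 * _COUNT_HALF, arr)
    if np.isscalar(value) or np.ndim(value) == 0:
        return int(out)
    return out.astype(np.int64)


def accel_lsb(config: PipelineConfig) -> float:
    """Accelerometer LSB size in m/s^2."""
    return config.accel_full_scale_g * G_STD / _COUNT_HALF


def gyro_lsb(config: PipelineConfig) -> float:
    """Gyroscope LSB size in rad/s."""
    return np.deg2rad(config.gyro_full_scale_dps) / _COUNT_HALF


def counts_to_si(accel_counts, gyro_counts,
                 config: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
    """Scale signed counts to SI units at the configured full-scale ranges."""
    a = np.asarray(accel_counts, dtype=float) * accel_lsb(config)
    g = np.asarray(gyro_counts, dtype=float) * gyro_lsb(config)
    return a, g


def counts_to_physical(sample: RawImuSample,
                       config: PipelineConfig) -> ImuRecord:
    """Convert one decoded sample to physical units.

    Acceleration scales as ``counts * full_scale_g * 9.80665 / 32768`` m/s^2
    and angular rate as ``counts * full_scale_dps * pi/180 / 32768`` rad/s.
    """
    a, g = counts_to_si(sample.accel_counts, sample.gyro_counts, config)
    return ImuRecord(accel=a, gyro=g, dt=config.dt)


# ---------------------------------------------------------------------------
# stream files
# ---------------------------------------------------------------------------

_NUM_RE = re.compile(r"^[+-]?(\d+\.?\d*|\.\d+)([eE][+-]?\d+)?$")


def _parse_lines(path: str | Path) -> np.ndarray:
    """Parse a whitespace- or comma-separated numeric table.

    One sample per line, six numeric fields (optionally preceded by an
    integer timestamp/index column), optional single header row.  Malformed
    lines are reported with their line number.
    """
    rows: list[list[float]] = []
    ncols: int | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text or text.startswith("#"):
                continue
            parts = [p for p in re.split(r"[,\s]+", text) if p]
            if not rows and not all(_NUM_RE.match(p) for p in parts):
                continue  # header row
            try:
                values = [float(p) for p in parts]
            except ValueError as exc:
                raise StreamParseError(
                    f"{path}: non-numeric field on line {lineno}") from exc
            if ncols is None:
                if len(values) not in (6, 7):
                    raise StreamParseError(
                        f"{path}: line {lineno} has {len(values)} fields, "
                        "expected 6 (ax ay az gx gy gz) or 7 (with a leading "
                        "timestamp column)")
                ncols = len(values)
            elif len(values) != ncols:
                raise StreamParseError(
                    f"{path}: line {lineno} has {len(values)} fields, "
                    f"expected {ncols}")
            rows.append(values)
    if not rows:
        raise StreamParseError(f"{path}: no samples found")
    arr = np.asarray(rows, dtype=float)
    if arr.shape[1] == 7:  # drop the timestamp/index column
        arr = arr[:, 1:]
    return arr


def _looks_like_counts(arr: np.ndarray) -> bool:
    """Heuristic for the unsigned-16-bit-counts dialect.

    Counts files contain only integers in [0, 65535], and any realistic
    stream carries negative noise excursions that encode as words >= 32768.
    Ambiguous files (e.g. all-zero) are treated as physical units; pass
    ``units`` explicitly when the heuristic cannot apply.
    """
    if not np.all(arr == np.round(arr)):
        return False
    return bool(arr.min() >= 0 and arr.max() <= 65535 and arr.max() >= 32768)


def read_stream(path: str | Path, config: PipelineConfig | None = None,
                units: str = "auto") -> ImuStream:
    """Read a six-axis IMU text/CSV stream.

    Parameters
    ----------
    path:
        Text file, one sample per line: ``ax ay az gx gy gz`` (whitespace or
        comma separated), optional leading timestamp column, optional header.
    units:
        ``"counts"`` — unsigned 16-bit ADC words, decoded and scaled through
        the configured full-scale ranges; ``"si"`` — accelerations in m/s^2
        and rates in deg/s or rad/s per ``config.gyro_in_degrees``;
        ``"auto"`` — counts if the file looks like unsigned integer words
        (see :func:`_looks_like_counts`), else SI.
    """
    config = config or PipelineConfig()
    arr = _parse_lines(path)
    if units not in ("auto", "counts", "si"):
        raise ValueError("units must be 'auto', 'counts' or 'si'")
    if units == "auto":
        units = "counts" if _looks_like_counts(arr) else "si"
    if units == "counts":
        signed = decode_counts(arr.astype(np.int64))
        accel, gyro = counts_to_si(signed[:, :3], signed[:, 3:], config)
    else:
        accel = arr[:, :3]
        gyro = arr[:, 3:]
        if config.gyro_in_degrees:
            gyro = np.deg2rad(gyro)
    return ImuStream(accel=accel, gyro=gyro, dt=config.dt)


def write_stream(path: str | Path, stream: ImuStream,
                 config: PipelineConfig | None = None,
                 units: str = "si") -> None:
    """Write a stream in the dialect :func:`read_stream` reads.

    ``units="si"`` writes full-precision floats (round-trips to <=1e-9
    relative error); ``units="counts"`` quantizes to unsigned 16-bit words.
    """
    config = config or PipelineConfig()
    header = "ax ay az gx gy gz"
    if units == "si":
        gyro = np.rad2deg(stream.gyro) if config.gyro_in_degrees else stream.gyro
        table = np.hstack([stream.accel, gyro])
        np.savetxt(path, table, fmt="%.12g", header=header)
    elif units == "counts":
        a = np.round(stream.accel / accel_lsb(config)).astype(np.int64)
        g = np.round(stream.gyro / gyro_lsb(config)).astype(np.int64)
        a = np.clip(a, -_COUNT_HALF, _COUNT_HALF - 1)
        g = np.clip(g, -_COUNT_HALF, _COUNT_HALF - 1)
        words = encode_counts(np.hstack([a, g]))
        np.savetxt(path, words, fmt="%d", header=header)
    else:
        raise ValueError("units must be 'si' or 'counts'")


def write_reference_csv(path: str | Path, t: np.ndarray, pos: np.ndarray,
                        vel: np.ndarray | None = None,
                        quat: np.ndarray | None = None) -> None:
    """Write a reference (ground-truth) trajectory: ``t,x,y,z[,vx..][,q0..]``."""
    import pandas as pd

    data = {"t": t, "x": pos[:, 0], "y": pos[:, 1], "z": pos[:, 2]}
    if vel is not None:
        data.update(vx=vel[:, 0], vy=vel[:, 1], vz=vel[:, 2])
    if quat is not None:
        data.update(q0=quat[:, 0], qx=quat[:, 1], qy=quat[:, 2],
                    qz=quat[:, 3])
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_reference_csv(path: str | Path):
    """Read a reference trajectory CSV; returns ``(t, pos, vel-or-None)``."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"t", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise StreamParseError(
            f"{path}: reference CSV needs columns {sorted(required)}")
    t = df["t"].to_numpy(float)
    pos = df[["x", "y", "z"]].to_numpy(float)
    vel = None
    if {"vx", "vy", "vz"}.issubset(df.columns):
        vel = df[["vx", "vy", "vz"]].to_numpy(float)
    return t, pos, vel
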