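"""Accelerometer sphere-model calibration and stream correction.

A stationary accelerometer measures only gravity, so readings taken at many
orientations should lie on a sphere of radius 1 g.  Per-axis scale and bias
deviations deform that sphere into an axis-aligned ellipsoid: with the
deviation model

    measured = L * (true + b)        (per axis; L diagonal, b in g units)

the measured static points lie on an ellipsoid with centre ``L b`` and
semi-axes ``diag(L)``.  The fit proceeds in the order the deviation model
suggests: first a least-squares sphere-centre fit with the scale assumed one
(linearising |x - c|^2 = r^2 into normal equations), then a second linear
pass for the per-axis scale with the centre removed, iterated a few times for
refinement.  Because a residual radius deficit remains even after fitting,
the corrected stream is finally rescaled so that the static-window mean norm
is exactly 1 g.

The gyroscope has no sphere constraint; its bias is estimated as the
static-window mean rate and subtracted (switchable), without which attitude
drift would dominate the reconstruction.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import (G_STD, DegenerateGeometryError, ImuStream, KickTrackError,
                 PipelineConfig)


@dataclass
class CalibrationModel:
    """Per-axis accelerometer deviation model plus gyro bias.

    ``scale`` is the diagonal of L (dimensionless), ``bias`` the centre
    deviation b in g units.  ``norm_factor`` is the stream-level radius
    rescale applied after inversion (mean static norm in g before the final
    normalisation; 1.0 until a stream has been calibrated).  ``gyro_bias``
    is in rad/s.
    """

    scale: np.ndarray = field(default_factory=lambda: np.ones(3))
    bias: np.ndarray = field(default_factory=lambda: np.zeros(3))
    norm_factor: float = 1.0
    gyro_bias: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.scale = np.asarray(self.scale, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        self.gyro_bias = np.asarray(self.gyro_bias, dtype=float)
        if self.scale.shape != (3,) or self.bias.shape != (3,):
            raise ValueError("scale and bias must be 3-vectors")
        if np.any(self.scale <= 0):
            raise KickTrackError("calibration scale must be strictly positive")
        if not np.all(np.isfinite(self.bias)):
            raise KickTrackError("calibration bias must be finite")

    @classmethod
    def identity(cls) -> "CalibrationModel":
        return cls()

    # -- persistence: small key-value text file ------------------------

    def save(self, path: str | Path) -> None:
        lines = []
        for axis, s, b, gb in zip("xyz", self.scale, self.bias,
                                  self.gyro_bias):
            lines.append(f"scale_{axis} {float(s)!r}")
            lines.append(f"bias_{axis} {float(b)!r}")
            lines.append(f"gyro_bias_{axis} {float(gb)!r}")
        lines.append(f"norm_factor {float(self.norm_factor)!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        values: dict[str, float] = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition(" ")
            values[key] = float(val)
        return cls(
            scale=np.array([values[f"scale_{a}"] for a in "xyz"]),
            bias=np.array([values[f"bias_{a}"] for a in "xyz"]),
            gyro_bias=np.array([values.get(f"gyro_bias_{a}", 0.0)
                                for a in "xyz"]),
            norm_factor=values.get("norm_factor", 1.0),
        )


def _fit_center(points: np.ndarray) -> np.ndarray:
    """Algebraic least-squares sphere centre of (n, 3) points.

    Linearises |x - c|^2 = r^2 as 2 c . x + (r^2 - |c|^2) = |x|^2 and solves
    the normal equations.  Raises for rank-deficient geometry (points on a
    plane or a line cannot pin the centre).
    """
    a = np.hstack([2.0 * points, np.ones((len(points), 1))])
    rhs = np.sum(points ** 2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(a, rhs, rcond=None)
    if rank < 4:
        raise DegenerateGeometryError(
            "calibration orientations are coplanar; the sphere centre is "
            "not identifiable")
    return sol[:3]


def _fit_scale(points: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Per-axis semi-axes of an axis-aligned ellipsoid about ``center``."""
    u = (points - center) ** 2
    w, _, rank, _ = np.linalg.lstsq(u, np.ones(len(points)), rcond=None)
    if rank < 3 or np.any(w <= 0):
        raise DegenerateGeometryError(
            "calibration orientations do not constrain all three axis "
            "scales")
    return 1.0 / np.sqrt(w)


def fit_sphere(static_samples, n_iter: int = 3) -> CalibrationModel:
    """Fit the deviation model ``measured = L (true + b)`` from static data.

    Parameters
    ----------
    static_samples:
        (n, 3) near-static accelerometer readings in g units, spanning at
        least four distinct, non-coplanar orientations; n >= 9.
    n_iter:
        Centre/scale refinement passes (the first pass is the classic
        "assume L = 1, fit the centre" step).

    Returns a model whose application maps the static samples to (nearly)
    unit-norm vectors; the residual radius deficit is handled later by the
    stream-level normalisation in :func:`calibrate_stream`.
    """
    pts = np.asarray(static_samples, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("static_samples must be (n, 3)")
    if len(pts) < 9:
        raise ValueError("need at least 9 static samples for a sphere fit")

    center = _fit_center(pts)              # first pass: L assumed one
    scale = np.ones(3)
    for _ in range(n_iter):
        scale = _fit_scale(pts, center)
        # refit the centre in scale-corrected space, map back to raw space
        center = scale * _fit_center(pts / scale)
    return CalibrationModel(scale=scale, bias=center / scale)


def apply_calibration(accel_g: np.ndarray,
                      model: CalibrationModel) -> np.ndarray:
    """Invert the deviation model on acceleration(s) in g units.

    Returns ``(a / L - b) / norm_factor``; with a freshly fitted model
    ``norm_factor`` is 1 and the stream-level rescale is added by
    :func:`calibrate_stream`.
    """
    accel_g = np.asarray(accel_g, dtype=float)
    return (accel_g / model.scale - model.bias) / model.norm_factor


def calibrate_stream(stream: ImuStream, model: CalibrationModel,
                     config: PipelineConfig
                     ) -> tuple[ImuStream, CalibrationModel]:
    """Apply a calibration model to a stream, with the final normalisation.

    Steps, in order:

    1. invert the accelerometer deviation model per sample (in g units);
    2. rescale the whole stream by the static-window mean norm, so the mean
       static gravity magnitude is exactly 1 g;
    3. subtract the static-window mean gyro rate if
       ``config.subtract_gyro_bias`` (the gyro-bias estimate).

    Returns the corrected stream (SI units) and a copy of the model with
    ``norm_factor`` and ``gyro_bias`` filled in as used.
    """
    if len(stream) < config.static_window:
        raise KickTrackError(
            f"stream has {len(stream)} samples, shorter than the "
            f"{config.static_window}-sample static window")
    accel_g = stream.accel / G_STD
    raw = accel_g / model.scale - model.bias
    norm_factor = float(
        np.mean(np.linalg.norm(raw[:config.static_window], axis=1)))
    if norm_factor <= 0:
        raise KickTrackError("static window has zero mean acceleration norm")
    accel_cal = raw / norm_factor * G_STD

    gyro_bias = np.zeros(3)
    if config.subtract_gyro_bias:
        gyro_bias = stream.gyro[:config.static_window].mean(axis=0)
    gyro_cal = stream.gyro - gyro_bias

    fitted = dataclasses.replace(
        model, norm_factor=model.norm_factor * norm_factor,
        gyro_bias=gyro_bias)
    return ImuStream(accel=accel_cal, gyro=gyro_cal, dt=stream.dt), fitted
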