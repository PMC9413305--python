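# Methods

This note records the model, the numerical choices and the limits of what
the package's validation does and does not show.  It is the maintainer's
account of decisions that are genuinely open; the README describes the
pipeline itself.

## Signal model and assumptions

A six-axis MEMS IMU (3-axis accelerometer, 3-axis gyroscope, 16-bit ADC per
axis) is rigidly attached to the instep and sampled uniformly at
`sample_rate_hz` (default 100 Hz).  The accelerometer measures specific
force — kinematic acceleration minus gravity, in the sensor frame — with a
per-axis linear deviation `G = L(g + b)` (diagonal L, bias b in g units)
plus white Gaussian noise and quantization.  The gyroscope measures body
rates with an additive bias and white noise.  Assumptions the pipeline
relies on:

* the recording starts with at least `static_window` samples at rest (the
  athlete stands still before the kick);
* samples are uniformly spaced at the configured rate — there is no
  timestamp-gap handling;
* rotation is tracked by gyro integration alone (no magnetometer), so
  orientation is only known relative to the initial static frame, and the
  heading (yaw) of the reconstructed world frame is fixed by convention,
  not observed;
* the movement is short (a few seconds of motion), so uncompensated
  noise-level drift stays small between zero-velocity updates.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `sample_rate_hz` | 100 | Hz | sensor output rate; all integrals use Δt = 1/rate |
| `accel_full_scale_g` | 30 | g | instep kicks peak near 12 g; headroom avoids clipping |
| `gyro_full_scale_dps` | 4000 | °/s | fast foot rotation during the swing |
| `static_window` | 500 | samples | 5 s averaging for gravity offset, calibration norm and gyro bias; noise on the offset falls as 1/√window |
| `accel_gate` | 0.392 | m/s² | zeroes vibration/wind/residual-gravity noise (target motion sits above ≈ 3.92 m/s²); 0.04 g |
| `vel_gate` | 0.196 | m/s | residual-velocity threshold inside detected static runs (see below) |
| `zupt_run_length` | 15 | samples | consecutive gated zeros (0.15 s) that declare a static state |

The gate thresholds are part of the study conditions this package
reproduces, not free knobs; they are exposed in `PipelineConfig` because a
different movement (gait, throwing) would need a different operating point.

## Numerical choices

* **Attitude stepping.**  The update is the first-order additive step
  `q += ½ q ⊗ (0, ω̄) Δt` with renormalisation after every step (not
  periodically).  The rate entering each step is the average of the two
  bounding samples, ω̄ = (ω_k + ω_{k−1})/2 — the same averaged-sample idea
  as the velocity integral.  An endpoint rule carries a half-sample
  attitude lag which, during the fast swing (~30 m/s² of specific force),
  dominates the velocity error; centring the step removes it.  For a
  constant axis the error is O(Δt²): 90° integrated at 100 Hz lands within
  0.1° (measured ≈ 2·10⁻⁴ °), and halving Δt quarters the error.
* **Calibration fit.**  Centre and scales are obtained by chained linear
  least squares (centre with L = I, then per-axis scales from the centred
  squares), iterated three times; the fit is invariant to sample order and
  raises on coplanar orientation sets, whose normal equations are rank
  deficient.  The residual radius deficit that survives any finite fit is
  removed by a per-stream rescale of the static-window mean norm to exactly
  1 g.  Per-stream (rather than one-time) normalisation was chosen because
  the deficit depends on the noise level of each recording.
* **Leveling.**  `roll = arctan2(offset_y, offset_z)`;
  `pitch = −arctan2(offset_x, √(offset_y² + offset_z²))`, which aligns the
  rotated gravity with +z to machine precision at any tilt.  The
  small-angle variant `−arctan(offset_x/offset_z)` (identical to first
  order, adequate below ~15°) is kept behind `exact=False`.  Yaw is set to
  zero: with no magnetometer the heading is unobservable, so the
  reconstructed frame can differ from a reference frame by a small rotation
  about z (second order in the mounting tilt; ~1° at 10° tilt).  This is
  the main error floor of the position RMSE.
* **Gating and ZUPT.**  The gate acts on the vector norm, never per axis,
  so retained samples keep their direction.  "Acceleration is zero" for the
  15-sample rule means zero after gating — exact zeros only exist
  post-gate.  Velocity is reset from detection onward (causal), not
  retroactively over the run; during the 14-sample latency the small
  velocity plateau persists and is visible in the `stationary` flags.  The
  0.196 m/s residual-velocity threshold is tied to the detected static
  state, where the reset already clamps any residual — a global clamp would
  flatten the slow start of the backswing.
* **Integration.**  Trapezoidal for both integrals (exact for
  piecewise-linear acceleration); the first sample reuses itself as its
  predecessor, equivalent to a rectangle rule for one step.
* **Degenerate inputs.**  Streams shorter than the static window, sideways
  sensors (no gravity z component), coplanar calibration sets and
  infeasible kick profiles raise typed errors; motionless tracks yield
  zero metrics rather than a phase-detection error.

## The simulator

`truth_trajectory` composes quintic-smoothstep segments (zero velocity and
acceleration at every join, hence C²) with a sin² speed pulse for the
forward swing: static lead (600 samples), a straight backswing ramp to the
commanded apex, a forward swing whose along-kick speed is
`v_peak sin²(πτ)` while z dips from the apex through the starting height
(the low point, where the speed peak lands by construction) and rises into
a follow-through, and a trailing rest (150 samples).  The commanded peak
speed and apex are met exactly; the forward displacement is solved by root
finding so the total path meets its target, then phase durations snap to
the sample grid (path perturbation ≤ one sample's travel, well inside 2%).
Defaults — path 3.63 m, peak 7.47 m/s, apex 0.756 m, 1.5 s of motion, 60°
of foot pitch sweep, 0.35 m pull-back, 0.05 m lateral excursion — are the
study conditions the acceptance script reproduces.

`imu_from_truth` rotates gravity and rates into the (tilt-mounted) sensor
frame, applies `G = L(g + b)`, adds seeded Gaussian noise and quantizes to
16-bit counts.  `NoiseModel.randomized(seed)` draws the study-level sensor:
σ_accel = 0.05 m/s², σ_gyro = 0.2 °/s, |b| ≤ 0.05 g, scales within 2% of
unity, mounting tilt ≤ 10°, gyro bias ≤ 0.2 °/s per axis.

What the simulator does *not* emulate: soft-tissue and strap wobble,
accelerometer/gyro axis misalignment and cross-axis sensitivity,
temperature drift, ball impact (the emulated movement is an empty kick,
with no contact transient), and timing jitter.  Passing the closed-loop
tests therefore shows the *algorithmic* chain is correct and
noise-robust at realistic sensor specs; it does not certify accuracy on a
human kick, where mounting compliance and model mismatch add error.

## Evaluation conventions

Reconstruction and truth share a timebase, so pairing is on the common
clock; the onset-alignment mode (first sustained 3-sample movement) exists
for external references that start at motion onset.  RMSEs are computed
from the truth's motion onset to the end of the record — including the
multi-second static lead would dilute them.  Position RMSE is the RMS of
3D point-to-point distances.  Velocity RMSE is taken along the kick
direction, with each track projected onto its own horizontal net-displacement
unit vector; this compares the along-kick speed profiles and does not
charge the yaw-convention mismatch (unobservable without a magnetometer)
against the velocity accuracy.  Bland–Altman statistics are per-axis on
paired positions with 95% limits at bias ± 1.96 SD, pooled counts reported.

Problem sizes used by the test suite and the acceptance script: kicks of
~900 samples (9 s at 100 Hz), ten seeds per closed-loop experiment, 600
calibration samples at 24 orientations, and 100 replicates of 240 pooled
pairs for the limits-of-agreement check.

## Known limitations

* Heading is conventional, not estimated; trajectories are comparable to a
  reference only up to a small rotation about gravity (handled by the
  along-kick velocity convention, visible as lateral position error).
* The calibration model is diagonal; cross-axis and misalignment terms are
  out of scope.
* The ZUPT acts only when the gated stream is exactly zero for the full
  run length; sustained sub-gate motion (slow drifting of the foot) is
  indistinguishable from rest.
* Backswing detection assumes the apex precedes the speed peak, which
  holds for instep kicks but not for arbitrary movements.
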