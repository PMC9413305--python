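# kicktrack

Reconstructs the 3D trajectory of a football instep kick from a **single
six-axis IMU** strapped to the instep, and extracts the metrics a coach or
sports scientist cares about: total path length, maximum foot speed (and
where on the swing it occurs), and the backswing apex height — a proxy for
how much the knee was loaded before the forward swing.  Camera-based motion
capture delivers these numbers too, but needs a calibrated volume and
expensive hardware; a 100 Hz accelerometer + gyroscope on the foot does not.

The package is aimed at wearable-sensing and human-movement researchers who
want a transparent, fully testable strapdown pipeline for short, explosive
movements, plus a simulator that generates ground-truth kicks so every stage
can be validated without recorded data.

## Method

Raw 16-bit sensor words are decoded (two's complement) and scaled at the
configured full-scale ranges (±30 g, ±4000 °/s by default).  The pipeline is
then:

1. **Sphere-model calibration.**  A static accelerometer at many
   orientations reads pure gravity, so its readings should lie on a sphere
   of radius 1 g.  With the per-axis deviation model `G = L(g + b)` (L
   diagonal scale, b bias, both in g units), the measured points lie on an
   ellipsoid; `fit_sphere` recovers L and b by two chained linear
   least-squares passes (centre first with L = I, then the per-axis scales),
   and the corrected stream is finally rescaled so the static-window mean
   norm is exactly 1 g.  The gyro bias is estimated as the static-window
   mean rate and subtracted.
2. **Quaternion attitude.**  Orientation relative to the initial (static)
   sensor frame is propagated from the body rates ω by the quaternion
   kinematic equation `q̇ = ½ q ⊗ (0, ω)`, stepped as
   `q_k = q_{k−1} + ½ q_{k−1} ⊗ (0, ω̄) Δt` with renormalisation after
   every step; accelerations rotate into the initial frame via
   `a' = q ⊗ (0, a) ⊗ q*`.
3. **Gravity and tilt.**  The mean specific force over the first 500 static
   samples is the gravity offset; it is subtracted everywhere, and its
   direction gives the roll/pitch of the initial frame
   (`roll = arctan(offset_y / offset_z)`, yaw ≡ 0).  The rotation
   `T = R_z R_y R_x` levels the frame so +z opposes gravity.
4. **Gated double integration with ZUPT.**  Accelerations whose norm falls
   below 0.392 m/s² are zeroed, then velocity integrates by the
   averaged-sample rule `v_i = v_{i−1} + (a_i + a_{i−1}) Δt / 2` (exact for
   piecewise-linear profiles) and position by the same rule on velocity.
   When 15 consecutive gated samples are zero the foot is declared static
   and the velocity reset to zero — the zero-velocity update that stops
   integration drift from leaking out of every movement (residual
   velocities below the 0.196 m/s threshold are clamped by the same reset).

The built-in simulator inverts an analytic, C²-smooth kick (static lead →
backswing to the commanded apex → forward swing peaking at the commanded
speed → follow-through to rest) into raw counts, through the same deviation
model, sensor noise, mounting tilt and quantization — so the whole chain can
be scored against exact ground truth.

## Worked example

```
$ kicktrack simulate --seed 1 --out demo/sim
wrote demo/sim/imu.csv, demo/sim/truth.csv, demo/sim/calibration_samples.csv

$ kicktrack reconstruct demo/sim/imu.csv \
    --calib-samples demo/sim/calibration_samples.csv --out demo/rec
{
  "path_length_m": 3.616382480366682,
  "max_speed_mps": 7.472827741526051,
  "max_speed_index": 718,
  "max_speed_position_m": [0.0557, 0.8423, 0.0108],
  "backswing_height_m": 0.7613564224447702,
  "backswing_apex_index": 686
}

$ kicktrack evaluate demo/rec/trajectory.csv demo/sim/truth.csv --out demo/eval
{
  "position_rmse_m": 0.007866271339273118,
  "velocity_rmse_mps": 0.0027222726716855804,
  ...
}
```

The simulated kick commanded a 3.63 m path, a 7.47 m/s peak and a 0.756 m
apex; the reconstruction recovers 3.616 m, 7.473 m/s (0.04% error, occurring
at the bottom of the swing, sample 718) and 0.761 m (0.7% error), with a 3D
position RMSE of 7.9 mm against the ground truth.  `evaluate` also prints
per-axis Bland–Altman bias and 95% limits of agreement; `--plot` writes the
3D-trajectory and Bland–Altman figures.

Reconstruction of real recordings works the same way: point `reconstruct`
at a six-column text/CSV stream (counts or physical units) preceded by a
static lead-in, plus a multi-orientation static capture for calibration.

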