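# hipkin

3D hip joint angles from body-worn magnetic-inertial sensors (MIMUs),
with no optical motion capture, no prescribed sensor orientation, and
only minimal calibration motions.

`hipkin` is aimed at biomechanics and wearable-sensing researchers who
want a fully inspectable pipeline from raw gyroscope / accelerometer /
magnetometer channels to flexion-extension (FE), ad/abduction (AA) and
internal-external rotation (IER) hip angle traces — together with a
rigid-body simulator that generates ground-truthed sensor data, so every
stage can be validated without recorded data.

## What it implements

1. **SSRO — sensor-to-sensor relative orientation.** A 10-state Kalman
   filter over `χ = [g1; g2; q21]`: the gravity direction in each sensor
   frame and the unit quaternion rotating thigh-sensor coordinates into
   the pelvis-sensor frame. Gravity propagates by `g ← (I − Δt[ω×])g`,
   the quaternion by `q ← (I₄ − (Δt/2)Ω(ω₂ − R21ᵀω₁))q`; measurements
   are the accelerometer direction (after an AR(1) body-acceleration
   correction) and a direct quaternion built by aligning the two gravity
   estimates and the gravity-orthogonal magnetic components. Because
   only the *shared* field enters, homogeneous magnetic disturbances
   cancel exactly.
2. **Functional calibration.** Joint centers from the ball-joint
   constraint `a₁ − ([ω₁×][ω₁×] + [ω̇₁×])r₁ = R21(a₂ − ([ω₂×][ω₂×] +
   [ω̇₂×])r₂)` stacked over ≥1500 high-angular-velocity samples and
   solved by least squares; knee (hinge) axes from
   `‖ω₁×j₁‖ = ‖ω₂×j₂‖`, with the quasi-1D knee center corrected along
   the axis.
3. **Anatomical alignment.** ISB-convention pelvis and thigh frames
   from the joint centers and the stillest window of a static standing
   trial; constant per sensor thereafter.
4. **Hip angles.** The ISB joint coordinate system (`e1` = pelvis Z,
   `e3` = thigh y, `e2 = e3×e1`) evaluated per sample from the SSRO
   orientation — with an exact forward/inverse construction used for
   verification.
5. **Metrics.** Wrapped-difference RMSE, regression slope/intercept,
   range of motion (with the start-up exclusion rule), and drift with a
   Wilcoxon helper.
6. **Simulator.** Analytic rigid-body kinematic chains (ball and hinge
   joints, mounting rotations, gravity, shared magnetic field, additive
   noise) whose pre-noise channels satisfy the joint constraint to
   ~1e-14, plus a full static + star-calibration + walking protocol.

See `docs/methods.md` for the model details, parameter table, and
limitations.

## Worked example

```python
import numpy as np
from hipkin.synthdata import simulate_protocol, DEFAULT_NOISE
from hipkin.hip_angles import run_pipeline
from hipkin.metrics import rmse

proto = simulate_protocol(seed=18, noise=DEFAULT_NOISE)
angles, calib = run_pipeline(proto.trials["static"], proto.trials["star"],
                             proto.trials["walking"])
for side in ("left", "right"):
    truth = proto.truth_angles["walking"][side]
    print(side, {k: round(rmse(getattr(angles[side], k), getattr(truth, k)), 2)
                 for k in ("fe", "aa", "ier")})
```

prints (noise seed 18; values in degrees)

```
left {'fe': 7.02, 'aa': 5.71, 'ier': 3.38}
right {'fe': 15.38, 'aa': 11.43, 'ier': 6.38}
```

i.e. the full pipeline — filter, functional calibration with randomized
sensor mountings, and angle extraction — recovers the prescribed walking
profiles with per-axis RMSE at the several-degree level. That is the
same magnitude this algorithm family achieves against optical motion
capture on real subjects; the dominant error source is body acceleration
at the sensors, not noise (see `docs/methods.md`). Re-running the
noiseless pipeline with different mounting orientations changes the
traces by under 1e-5 degrees RMS: the method is placement-robust by
construction.

A command-line interface mirrors the library:

```bash
hipkin simulate --seed 1 --out protocol/          # write protocol CSVs
hipkin ssro --imu1 pelvis.csv --imu2 thigh.csv --out q21.csv
hipkin calibrate --static-dir protocol/static --dynamic-dir protocol/star --out calib.yaml
hipkin angles --calib calib.yaml --pelvis pelvis.csv --thigh thigh.csv --side right --out angles.csv
hipkin evaluate --est angles.csv --ref truth.csv
```

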