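# Methods

`hipkin` estimates 3D hip joint angles from two (plus optional auxiliary)
body-worn magnetic-inertial measurement units (MIMUs). This note records
the model, the numerical choices, the synthetic study conditions, and the
known limitations, so that every number the tests and the acceptance
script print can be interpreted.

## Sensor-to-sensor relative orientation (SSRO)

The core estimator is a 10-state Kalman filter over
`chi = [g1; g2; q21]`: the unit gravity direction in each sensor frame
and the unit quaternion rotating sensor-2 coordinates into the sensor-1
frame (`v1 = q21 ⊗ v2 ⊗ q21⁻¹`). No world frame is ever constructed; the
magnetic field enters only through the assumption that both sensors see
the *same* field expressed in their own frames, so homogeneous magnetic
disturbances cancel identically (verified to machine precision by the
field-equivariance test).

**Time update.** Gravity vectors propagate by the rigid-rotation rule
`g ← (I − Δt[ω×])g` and the quaternion by the first-order body-rate rule
`q ← (I₄ − (Δt/2)Ω(ω_diff))q` with `ω_diff = ω2 − R21ᵀω1`; both are
renormalized every step because the linear update does not preserve
norms. The 4×4 operator `Ω` is defined so that `Ω(ω)q = −(q ⊗ [0, ω])`,
which makes the update exactly the body-rate kinematics
`q̇ = ½ q ⊗ ω_diff`. A pure prediction run tracks 60 s of noiseless
moderate 3D motion to better than 1°, so first-order integration is not
the accuracy bottleneck.

**Process noise.** `Q_g = Δt² σω² [g×][g×]ᵀ` per sensor and
`Q_q = Δt² σω² Ω(q)Ω(q)ᵀ = Δt² σω² I₄` for a unit quaternion. The
symmetrized products are used because the raw two-sided product of the
(non-skew) quaternion operator is not a covariance; for the gravity
blocks the two forms coincide.

**Measurements.** Two measurements are fused at every sample:

1. *Gravity:* `ζ_g = a_k − c·ã_{k−1}` with observation matrix `G·I₃`,
   where `ã = a − G·g` is the running true-(body-)acceleration estimate
   and `c` is the AR(1) constant of the body-acceleration model. Its
   noise covariance is `σa² I₃ + (c²/N) Σ ã ãᵀ` over a moving window of
   `N` samples that grows from 1 at the start of a trial.
2. *Quaternion:* a direct vector-matching construction. The half-angle
   rotation taking `ĝ2` onto `ĝ1` is composed with a heading rotation
   aligning the gravity-orthogonal (normalized) magnetic components.
   When the two horizontal components are antiparallel the heading axis
   is taken as the gravity direction (the half-turn is well defined
   there); truly degenerate geometry (field parallel to gravity) raises.
   Its noise is `μ(‖ã1‖² + ‖ã2‖²) I₄`, so the filter leans on gyro
   integration during dynamics and on the vector measurement when the
   body acceleration is small. The measured quaternion's sign is flipped
   to the hemisphere of the predicted quaternion before the update.

**Parameters** (defaults; `KFParams` or a YAML config with keys
`sigma_w, sigma_a, c, n_ma, mu, g`):

| name | default | units / role |
|---|---|---|
| `sigma_w` | 1e-3 | gyro noise parameter; enters Q as `sigma_w²` |
| `sigma_a` | 6e-3 | accelerometer noise parameter; enters M as `sigma_a²` |
| `c` | 0.003 | AR(1) constant of the true-acceleration model |
| `n_ma` | 64 | moving-average window (samples) for the adaptive noise |
| `mu` | 5e-8 | quaternion measurement error factor |
| `g` | 9.81 | gravitational acceleration, m/s² |
| `p0` | 1e-2 | initial covariance scale |

The `sigma` values are the reference tuning for Opal-class MIMUs resting
on a stationary surface. Two readings of the noise expressions are
possible (the values as variances used directly, or as parameters that
the covariance expressions square); the squared form is implemented
because it is what the model equations state and it is the only reading
under which `mu` plays its described balancing role. With `c = 0.003`
the AR(1) model treats body acceleration as nearly unpredictable, so the
gravity measurement is essentially the raw accelerometer direction and
the `n_ma` window term is numerically negligible; alternative readings
that strengthen the AR compensation were evaluated and found unstable
(see Limitations).

**Initialization** uses the mean of the first 64 samples (0.5 s at
128 Hz): gravity from the normalized mean accelerations, the quaternion
from the direct measurement on those means, `P0 = 1e-2·I₁₀`, and a
zeroed true-acceleration history (so the first update trusts the
quaternion measurement fully). Starting a trial mid-motion therefore
leaves an initialization error that the filter removes within about 2 s;
all reported SSRO error statistics exclude this 2 s warm-up, the same
convergence window the static accuracy check uses.

**Accuracy and lever arms.** After warm-up, the dominant error source is
body acceleration at the sensors: the gravity estimate behaves as a
~0.26 Hz low-pass of the accelerometer direction, so tangential and
centripetal acceleration proportional to the sensor's offset from the
joint corrupts it. With body-realistic offsets (thigh sensor 0.2–0.26 m
from the hip center) the 60 s walking-like simulation yields ~11° RMS
axis-angle error — almost exactly the RMSE this filter family reports
against optical motion capture on real subjects — while a compact rig
(1–2 cm offsets) yields ~0.8–0.9° with no measurable drift. Both numbers
are computed by the acceptance script.

## Preprocessing

All channels are zero-phase low-pass filtered (4th-order Butterworth,
forward–backward, 15 Hz). Angular acceleration is the second-order
central difference of angular velocity (one-sided at the endpoints, so
the array length is preserved) followed by a 12 Hz zero-phase filter.
Angle traces are resampled to a reference rate by linear interpolation;
orientation traces are never resampled.

## Functional joint centers and hinge axes

For a shared ball joint, the joint-center acceleration computed from
either sensor must agree up to the relative rotation, giving for each
high-motion sample a 3×6 block row in an overdetermined linear system in
the constant center-to-sensor vectors `r1` (sensor-1 frame) and `r2`
(sensor-2 frame). At least 1500 samples are used, ranked by the sum of
the two gyro norms (ties to earlier samples) and solved by least
squares. A design-matrix condition number above 1e8 raises a
degenerate-motion error: single-axis motion leaves the component of the
center along the axis unconstrained, and a segment that does not rotate
contributes zero columns for its own offset vector.

Hinge (knee) axes solve
`min Σ (‖ω1×j1‖ − ‖ω2×j2‖)²` with each axis in spherical coordinates
(unit norm by construction), BFGS from eight deterministic diagonal
starts, keeping the best optimum; polarity is fixed by requiring the two
axis-projected angular velocities to be positively correlated. The knee
center estimate is then shifted along the axes so the two axial
components balance (`r1·j1 + r2·j2 = 0`), the point on the axis nearest
the two sensors.

In the pipeline, the per-sample `R21` for the stacked system comes from
the SSRO filter. SSRO orientation bias during the calibration trial
(degrees, see above) propagates into the centers at the 10–45 mm level
with realistic geometry; with exact orientations the recovery is
exact to well under a millimetre (both are measured by the tests).

## Anatomical calibration and hip angles

The pelvis fixed axis `e1` is the unit vector from the left to the right
hip center in the pelvis sensor frame; each thigh fixed axis `e3` is the
unit knee-to-hip (proximal) vector in its thigh sensor frame. During the
stillest window of the static trial (1 s, minimum summed sliding
variance of the gyro/accel norms, ties to the earliest window) the thigh
axes are rotated into the pelvis sensor frame, `e2 = e3 × e1` per side,
and orthonormal right-handed frames are assembled: pelvis
`Z = e1`, `X = normalize(½(e2,left + e2,right))`, `Y = Z×X`; thigh
`y = e3`, `x =` that side's `e2` rotated back into the thigh sensor
frame by the still-pose SSRO quaternion, `z = x×y`. Secondary axes are
re-orthogonalized; a left-handed result raises rather than silently
flipping (it indicates a side-labeling error). The frames are constant
per sensor thereafter.

Hip angles follow the ISB joint coordinate system: `e1 =` pelvis Z,
`e3 =` thigh y, floating axis `e2 = e3×e1`; flexion(+)/extension(−) from
`atan2(η‖X×e2‖, X·e2)` with `η = sign((X×e2)·Z)`, internal/external
rotation analogously about the thigh axes with a side-dependent sign,
and ad/abduction `β = ∓π/2 ± arccos(e1·e3)` (right/left; the left branch
is the mirror of the right). This decomposition is an intrinsic Z-X-Y
Euler sequence; the forward construction
`R = Rz(α)·Rx(∓β)·Ry(±γ)` (right/left) inverts it to micro-degree
precision away from the `|β| = 90°` singularity, which raises a
singular-pose error.

## The simulator and the study conditions

The simulator builds a kinematic chain analytically: prescribed joint
angle profiles (sums of sinusoids with analytic first and second
derivatives), exact body angular velocity and acceleration via the
Euler-rate map and its derivative, and sensor channels
`gyro = Mᵀω`, `accel = Mᵀ(R_segᵀ(p̈ − g_world) + [ω̇×]s + [ω×][ω×]s)`,
`mag = MᵀR_segᵀ m_world` for mounting rotation `M` and sensor position
`s`. Pre-noise data satisfy the ball-joint acceleration identity to
~1e-14 (the simulator's defining contract, checked each run). Noise is
additive white Gaussian per channel, defaults gyro 0.005 rad/s, accel
0.08 m/s², mag 0.01 (units of the unit field) — chosen as plausible
consumer-MIMU noise floors, not vendor-specified values. The default world
field is a unit vector at 60° downward inclination; all behavior is
verified independent of the field direction short of vertical.

The three-trial protocol mirrors a typical study: 30 s quiet standing;
a ~55 s calibration trial of slow multi-plane hip sweeps (35/20/15° at
0.15–0.25 Hz) overlaid with a quick low-amplitude oscillation
(8–10° at 1.2–1.7 Hz) plus deliberate pelvis wobble — the oscillation
supplies the angular-acceleration richness that functional joint-center
estimation needs on both segments; and 60 s of walking-like motion
(FE 30° at 1 Hz with 8° AA/IER components, small pelvis sway and
1–1.5 cm translation bounce). Sensors: posterior lumbar
(−0.10, 0.05, 0) m in the pelvis frame, lateral mid-thigh
(0.02, −0.25, ±0.06) m from the hip, anterior shank (0.04, −0.12, ∓0.06) m
from the knee, with seeded random mounting rotations. The thigh/shank
axial offsets are equal and opposite so the hinge-correction's midpoint
assumption holds exactly in simulation; real placements bias the knee
center along the flexion axis by half the axial offset sum.

**What the simulator does not model:** soft-tissue artefact, gyro bias
or scale error, magnetic field gradients between sensors, and foot
impacts sharper than the prescribed sinusoids. Passing tests therefore
demonstrate algorithmic correctness under the rigid-body, shared-field
assumptions — not clinical accuracy. Conversely, because gyro bias is
absent, pure integration looks better here than on real hardware; the
reference filter tuning assumes real hardware.

## Agreement metrics

Angle differences are wrapped to (−180°, 180°] before any statistic.
RMSE is the root of the mean squared wrapped difference (the printed
definition of its source omits the square; "root mean square" is
implemented as named). Regression is OLS of the estimate on the
reference (slope within 0.1 of 1 is excellent, 0.3 good, 0.5 moderate).
Range of motion is max−min, excluding the first 10 s of trials longer
than 30 s (strictly greater). Drift is the OLS slope of the wrapped
error against time; a helper applies the two-sided Wilcoxon signed-rank
test (exact for n ≤ 25) to a sample of per-subject drift slopes.

## Known limitations

* With the reference parameters the gravity measurement has no effective
  body-acceleration compensation (`c = 0.003` makes both the AR
  prediction and the adaptive window term negligible), so orientation
  accuracy degrades linearly with sensor lever arm during sustained
  motion. Strengthened-compensation variants (AR coefficient near 1, or
  an unscaled adaptive window) were evaluated and are unstable with this
  state parameterization; the reference values are kept.
* Calibration quality inherits that orientation bias: with realistic
  geometry, joint centers carry centimetre-level errors and the final
  angle RMSE lands at the several-degree level the method also reports
  against optical motion capture in vivo — not at the sub-degree level
  an idealized filter would suggest.
* The hinge-center correction assumes the true joint center lies midway
  between the sensors' axial positions; the protocol geometry satisfies
  this by construction, real placements only approximately.
* One-sided endpoint differences make the first/last angular-acceleration
  samples first-order accurate; calibration never depends on endpoints.
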