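# Methods

This note documents the generative model, the two kinematic models, the
signal-processing and statistics choices, the default parameters, and the
known limitations of the simulation.

## Coordinate conventions

World and torso frames use X anterior, Y upward, Z toward the subject's
right; rotation matrices store axis directions as columns. All angles are
reported in degrees.

## Motion model

Each functional task is a point-to-point joint-space movement between a
start posture and a goal posture in the four channels
(shoulder flexion/extension `shoulder_fe`, adduction/abduction
`shoulder_aa`, internal/external rotation `shoulder_ie`, elbow flexion
`elbow_fe`). The time course follows the minimum-jerk profile

    s(τ) = 10τ³ − 15τ⁴ + 6τ⁵,  τ = t / T,

which has zero velocity and acceleration at both ends — a standard model of
smooth, goal-directed reaching. Optional within-trial variability adds a
seeded, smooth, endpoint-preserving perturbation (a short sine series
`Σ aⱼ sin(jπτ)` with `aⱼ ~ N(0, (sd/j)²)`, 4 harmonics), so start and goal
postures are never disturbed.

Default task postures place the goal at physiologically plausible angles
for the four tasks (hand to contralateral shoulder, hand to mouth, combing
hair, hand to back pocket); the combing task is the most demanding in
elevation and axial rotation, the back-pocket task uses shoulder extension
and external rotation. Trials can be framed by a `lead_in`/`lead_out`
(default 0.5 s in the study pipeline) during which the start/goal posture
is held, so that conditioning filters see stationary ends and the movement
onset is visible to the lag estimator.

## Forward model (rendering)

A torso–upper-arm–forearm chain (`BodyPose`) converts an angle frame into
3-D geometry using subject anthropometry (segment lengths, shoulder width,
torso height; sampled per subject with 6 % coefficient of variation in the
study pipeline). The same pose is rendered for both devices:

* **Marker device (100 Hz).** Torso markers (C7, T10, CLAV, STRN), anterior
  and posterior shoulder markers, the four removable anatomical landmarks
  (lateral/medial epicondyle EL/EM, radial/ulnar styloid RS/US), and two
  rigid three-marker clusters on the upper arm (PUA1–3) and forearm
  (DUA1–3). `strip_landmarks=True` removes EL/EM/RS/US from the dynamic
  trial, as in a cluster-based capture protocol, leaving them only in the
  static calibration trial. Isotropic Gaussian noise (default 0.5 mm SD)
  models optical residuals.
* **Skeleton device (30 Hz).** Tracked joints (SpineShoulder, SpineMid,
  shoulders, ElbowRight, WristRight, HandRight, Head) sampled on an
  unsynchronized clock delayed by a per-trial offset drawn from
  U(0.05, 0.4) s, with isotropic joint position noise (default 5 mm SD).

### Device systematic error model

The depth camera's characteristic angle errors are injected *before*
forward-rendering the skeleton joints, via two per-channel parameters:

* `angle_bias` — the error at the goal posture (the device's PTA bias);
* `angle_rom_bias` — the error of the movement excursion (ROM bias).

The device's rest offset is `o = bias − sign(excursion) · rom_bias`, and
the instantaneous offset relaxes from `o` to `bias` along the minimum-jerk
progress of the trial. With `rom_bias = 0` this reduces to a constant
offset; a negative `rom_bias` on a positive excursion compresses the
apparent range of motion, which is exactly how consumer depth cameras fail
on axial shoulder rotation — the transverse-plane channel keeps a plausible
goal angle but traverses far less excursion, which collapses waveform
similarity (CMC) in that plane while leaving the sagittal plane nearly
intact.

In addition, smooth per-channel stochastic angle noise (white noise
Gaussian-smoothed to ≈1.5 Hz bandwidth, rescaled to an exact per-sample SD)
models frame-to-frame tracking error. Finally the perturbed angles are
clamped to anatomically representable ranges
(±178°, ±88°, ±118°, 2–149°); the adduction clamp keeps perturbed postures
away from the |adduction| = 90° gimbal branch so the rendered device never
emits wrap artifacts.

## Inverse kinematics

**Marker model.** The torso anatomical frame comes from C7/T10/CLAV/STRN;
the upper-arm frame from the shoulder joint centre (mid anterior/posterior
shoulder markers), the elbow axis (EL–EM) and the elbow joint centre
(EL/EM midpoint); the wrist centre is the RS/US midpoint. A calibrated
anatomical-landmark technique (CAST) recovers the removable landmarks
during movement: the static trial expresses each landmark in its cluster's
technical frame (Procrustes fit of the three cluster markers); each dynamic
frame re-poses those local coordinates. The calibration residual (RMS of
the cluster self-fit) is reported and is ~1e−16 m noise-free.

**Skeleton model.** The torso frame uses SpineShoulder/SpineMid for the
vertical axis and the shoulder line for the lateral direction; the anterior
axis is their cross product. This differs from the marker torso frame
(which uses sternum markers for the anterior direction) but agrees with it
exactly in the noise-free rendered geometry.

**Shoulder angles.** The rotation of the humerus frame relative to the
torso frame is decomposed with the intrinsic Z–X–Y sequence
(flexion about Z, then adduction about X, then internal rotation about Y);
positive = flexion, adduction, internal rotation. Frames within 1° of
|adduction| = 90° are flagged as gimbal-degenerate. **Elbow flexion** is
computed from the joint centres as
`180° − arccos(unit(S−E) · unit(W−E))`, i.e. 0° = straight arm.

Both models recover the ground-truth angle channels to < 0.5° RMSE
noise-free for all four tasks (in practice ~1e−14).

## Signal conditioning

* Zero-phase low-pass Butterworth (order split across the forward and
  reverse passes of `filtfilt`; default 4th order, 6 Hz cutoff) — standard
  for human movement and phase-distortion-free.
* Cubic-spline (`scipy.interpolate.CubicSpline`) upsampling of both devices
  to a common 300 Hz grid; splines preserve the smooth kinematics far
  better than linear interpolation at a 30 Hz source rate.
* Clock alignment by brute-force cross-correlation: at each candidate shift
  the overlapping segments are *each* centred on their own mean before the
  normalized dot product (a per-shift Pearson correlation). Removing one
  global mean instead biases the peak on ramp-plateau-shaped signals, which
  functional reach angles are. Positive lag means the second signal trails
  the first.
* Time normalization of the movement to 101 points (0–100 % cycle) before
  waveform statistics.

## Agreement statistics

* **CMC** — coefficient of multiple correlation over waveforms
  (trials × 101 points): `sqrt(1 − MS_within / MS_total)`; a negative
  radicand (between-device difference exceeding waveform excursion) is
  reported as 0.0 with a `complex` flag, following the "complex CMC"
  convention.
* **RMSE** — pointwise waveform RMSE in degrees.
* **Discrete parameters** — angle at the point of target achieved (PTA,
  the frame of maximum task-defining excursion) and range of motion (ROM),
  compared by mean bias, Pearson r and two-sided paired t-test.
* **ICC** — two-way mixed, average measures over the subjects × sessions
  matrix: consistency `(MSB − MSE)/MSB` and absolute agreement
  `(MSB − MSE)/(MSB + (MSS − MSE)/n)`; absolute agreement is the headline
  reliability number since a session-level shift should count against
  reliability. Both match `pingouin`'s ICC(C,k)/ICC(A,k) to 1e−10.

## Study pipeline and default parameters

The default simulated study is 10 subjects × 2 sessions × 4 tasks ×
5 trials. All randomness derives from a single study seed through
`numpy.random.SeedSequence` spawning, so any subject/session/task/trial is
reproducible in isolation. Posture offsets are hierarchical Gaussians:
between-subject SD 6°, between-session SD 3°, within-trial SD 2°, plus
smooth within-movement variability (SD 1.5°) and duration jitter
(SD 0.15 s).

The per-task default `angle_bias` and `angle_rom_bias` tables encode the
characteristic depth-camera discrepancies (e.g. overestimated shoulder
flexion at the goal for hand-to-mouth/combing, underestimated elbow
flexion, compressed internal/external-rotation excursion). The stochastic
`angle_noise_sd` table can be calibrated from target waveform RMSE values
with `noise_tables_from_waveform_rmse`, which subtracts the systematic
contribution of the bias ramp — mean square `(o² + o·b + b²)/3` for a
linear ramp from rest offset `o` to bias `b` — and clamps at zero when the
systematic part alone meets or exceeds the target.

Problem sizes (cohort size, trial counts, rates of 100/30/300 Hz, 101-point
normalization, 6 Hz cutoff) are package defaults chosen to mirror common
practice in upper-limb validity studies; all are configurable through
`StudyConfig`.

## Limitations

* No soft-tissue artifact: marker clusters are perfectly rigid, so CAST
  reconstruction is exact up to optical noise.
* No marker occlusion/dropout or skeleton joint loss; trials are complete.
* Waveform conditioning ignores the gimbal masks (the clamping above keeps
  rendered data away from the singularity, but user-supplied data near
  |adduction| = 90° will pass through the filters unflagged).
* PTA extraction selects an extremum of the conditioned waveform; under
  stochastic angle/position noise this induces a small selection bias
  (an extremum of a noisy signal over-shoots), so recovered goal biases at
  realistic noise are attenuated/inflated by up to ~1.5° relative to the
  injected values.
* The skeleton device model perturbs joint *angles* then re-renders
  positions; real depth cameras err in joint positions directly, with
  depth-dependent, anisotropic noise that is not modelled.
* Anthropometry is scaled isotropically from segment lengths; no individual
  bone geometry or shoulder-rhythm (scapulothoracic) articulation.
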