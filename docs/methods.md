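# Methods

This note documents the models, conventions, parameter choices and known
limitations of `sparsepose`.

## Problem setting and assumptions

The task is snapshot full-body pose estimation: given the fused
orientations (unit quaternions, scalar-first) of five body-worn inertial
sensors at one instant, estimate the orientations of all 23 body segments
of a kinematic tree rooted at the pelvis. Assumptions inherited from the
approach:

* **Snapshot estimation.** Each frame is estimated independently; no
  temporal model couples consecutive poses. Estimated sequences therefore
  jitter frame-to-frame; temporal priors are deliberately out of scope.
* **Pelvis referencing.** All orientations are expressed relative to the
  pelvis segment, which removes the body's global heading and makes poses
  comparable across trials and subjects. Global position/heading tracking
  is out of scope; all joint positions are pelvis-relative.
* **Independent body halves.** Upper- and lower-body segments are
  estimated by separate models from the measured segments of their own
  half (plus the shared pelvis reference) and recombined. This implicitly
  assumes weak upper/lower coupling, which is reasonable for activities of
  daily living and effectively enlarges the space of representable
  full-body poses.
* **No biomechanical constraints.** Outputs are not corrected for joint
  limits; implausible poses are possible and intentionally left visible.

## Quaternion conventions

Components are scalar-first `(w, x, y, z)`. `q` and `−q` encode the same
rotation; every distance and every average is made double-cover safe:

* the shortest angle between orientations is
  `2·arccos(|scalar part of a⁻¹ ⊗ b|)`, which lies in [0, π] and is
  invariant to sign flips of either argument. The literal signed variant
  (range [0, 2π]) is available behind `absolute=False` for comparison but
  is not a metric on rotations;
* the arccos argument is clamped into [−1, 1]; near-identical orientations
  otherwise produce NaN. A consequence of arccos conditioning is that
  "identical" orientations can report angles up to ~3·10⁻⁸ rad — tests
  and consumers must not expect better from the angle itself;
* quaternion streams are sign-aligned frame-to-frame inside each trial
  when the database is built, and neighbor sets are sign-aligned to the
  nearest neighbor before averaging.

## Skeleton and kinematics

The 23-segment tree (pelvis; L5–L3–T12–T8 spine chain; neck, head;
shoulders, upper arms, forearms, hands; upper legs, lower legs, feet,
toes) stores, per non-root segment, the offset vector from the parent's
joint to the segment's joint in the parent's calibration frame. Forward
kinematics pins the pelvis joint at the origin and propagates
`pos(child) = pos(parent) + R(q_parent)·offset(child)`.

No published anthropometric table accompanies the approach, so the
template offsets are a synthetic stand-in for a 1.77 m adult (the study
population's mean height); skeletons are user-replaceable YAML data and
scale uniformly with subject height.

Joint angles decompose the relative orientation `q_prox⁻¹ ⊗ q_dist` with
an intrinsic Z–X–Y Euler sequence (flexion/extension,
abduction/adduction, internal/external rotation). The decomposition order
is a convention, not part of the method, and is configurable; middle
angles near ±90° are flagged (gimbal proximity) but not fatal. Angle
errors are wrapped to [0°, 180°] so that 170° vs −170° counts as 20°.

## Nearest-neighbor estimator

Distances are the mean shortest angle over the measured segments of one
body half (the pelvis, being the identity after referencing, is excluded
from features — it carries no information). The k nearest database poses
are combined componentwise with weights `(max(d) − d_n) / Σ(max(d) − d_n)`
and each output quaternion is renormalized. Design choices:

* **Weight scope.** The weight formula is evaluated over the k-nearest
  set so weights sum to 1 there; the literal whole-database normalization
  is available as `weight_scope="database"`. With distinct distances the
  farthest of the k always receives weight 0.
* **Degenerate weights.** When all k distances are equal (including k=1)
  the formula is 0/0; the continuous-limit fallback is uniform 1/k.
* **k=1 short-circuit.** With a single neighbor the weighted average *is*
  that neighbor; the stored row is returned verbatim, so querying a
  training pose recalls it bit-exactly.
* **Averaging.** The componentwise weighted sum plus normalization is kept
  (rather than an eigendecomposition-based rotation mean) for fidelity to
  the approach, with neighbor sign alignment added as the minimal fix that
  makes the sum well defined across the double cover.
* **Search.** Exhaustive linear scan; ties at the k-th neighbor break by
  lower database index (stable sort), making predictions invariant to
  database permutation.
* **Default k = 500**, the cross-validated optimum reported for the
  original two-hundred-thousand-pose database. On the much smaller
  synthetic database the subject-wise cross-validation harness typically
  selects a smaller k; the default is a starting point, not a claim.

## Neural-network estimator

A function-fitting network: tanh hidden layers (default 250 and 100
units), linear output, mean-squared-error loss on raw quaternion
components. Output norms are *not* constrained during training; predicted
4-tuples are normalized at inference. Training details:

* **Optimizer.** Full-batch Adam (learning rate 0.01), implemented
  in-package in pure numpy. The original toolbox used scaled conjugate
  gradient; the contract kept here is the loss/stopping behavior —
  full-batch updates, an epoch cap, a gradient-based stall stop and
  best-validation-weight selection — not the optimizer identity.
* **Stopping.** Training ends at 1000 epochs, or when the gradient norm
  has not decreased for 6 *consecutive* epochs (the counter resets on any
  decrease). Both thresholds are configurable. The phrase "gradient
  stopped decreasing" is ambiguous in its source; this reading is
  documented here rather than asserted as the original semantics.
* **Model selection.** A deterministic 10 % validation split (seeded)
  tracks the best weights seen; with `validation_fraction=0` the training
  loss is tracked instead.
* **Preprocessing.** Inputs are standardized per feature; the constants
  are stored on the model artifact. The original toolbox's input scaling
  is unstated; standardization is this package's choice.
* **Reproducibility.** Initialization (Glorot uniform) and the validation
  split derive from `random_state`; training is bit-reproducible given the
  seed, which is stored in the saved artifact.

## Sensor configurations

Five sensors, always including the pelvis, two per body half.
Configurations A ("pelvis, upper legs, upper arms") and E ("pelvis, right
upper and lower arm, right upper and lower leg") follow their published
textual definitions. B, C, D and F were defined only graphically in the
source material; the shipped presets are documented placeholders (D =
pelvis, forearms, lower legs, matching the worked pipeline example) and
are replaceable via YAML files. When sensors sit on adjacent segments the
spanned joint's angle error is identically zero and the corresponding
child-joint position error vanishes — a structural property the
evaluation tests exploit.

## Heading-noise model

Fused inertial/magnetometer orientation tracking observes inclination
(gravity-referenced roll/pitch) accurately; magnetic disturbances corrupt
heading. The model:

* draws white (time-uncorrelated) heading errors, Gaussian with default
  σ = 4.51° — the published yaw spread from a two-hour reference field
  recording (the recording itself is not available; inclination spreads
  were ≈ 0.47°/0.51° and are not simulated, as the approach perturbs
  heading only);
* premultiplies raw sensor orientations by a rotation about the global
  vertical, which preserves inclination exactly;
* applies noise to **test data only**, on the *raw* orientations before
  pelvis referencing, so pelvis heading error propagates into every
  referenced feature — the physical disturbance path;
* draws independently per sensor and per frame by default; whether the
  original analysis shared one draw across sensors is unstated, so a
  `shared_across_sensors` option covers both readings.

The sensitivity sweep re-runs the database pipeline per noise level with
fresh draws; the σ=0 level is an exact no-op (identity premultiplication)
and reproduces the clean evaluation bit-for-bit.

## Synthetic data generator

The generator emulates the study protocol at desk scale: 6 subjects ×
3 trials (one per activity style: cyclic gait, ADL-like, sport-like) ×
2500 frames at 240 Hz; the standard factor-10 downsampling yields 4500
database poses. Subject skeletons scale by factors drawn with the study
population's relative height spread (7.2/177.2 ≈ 4 %).

Per style, a fixed random mixing matrix maps four band-limited latent
signals (default bandwidth 1 Hz) to all local joint rotations; the map is
shared across subjects while latent realizations, small per-segment
smooth noise (0.05 rad), skeleton scale and gait parameters vary. This
builds in the method's learnability premise — similar input features
imply similar full-body poses, within and across subjects — which the
tests verify as a positive rank correlation between feature and pose
distances. Gait-style legs are deterministic sinusoidal patterns scaled
by a slow aperiodic stride envelope; the left-side series is the
right-side series shifted by exactly half a gait period (240 frames), so
left/right symmetry holds bit-exactly while no two frames repeat (exact
duplicates would make bit-exact nearest-neighbor recall ambiguous).
Per-frame local rotation increments are clamped at 3°/frame, giving a
provable bound on adjacent-frame global rotation via the bi-invariance of
the rotation metric.

What the generator does **not** emulate: muscle dynamics, ground contact,
soft-tissue artifact, sensor-fusion error structure, or the error
magnitudes of real recordings. Passing tests show the estimators and
harness behave correctly on data with the assumed statistical structure;
they do not certify centimeter-level accuracy on real human movement,
which depends on undeposited recordings.

## Problem sizes and numerical choices

Tests and the acceptance script run the full default database (4500
poses: 3750 training, 750 held-out frames from the left-out subject) for
learner-level checks, and a 3-subject × 600-frame variant (540 poses) for
unit-level checks — sizes chosen so the whole suite completes in about a
minute while preserving the multi-subject, multi-activity structure.
Cross-validation sweeps k over {25, 100, 250, 500} with one subject per
fold. Unit-norm tolerances are 10⁻⁹ after normalizing operations; file
readers accept quaternions within 10⁻³ of unit norm and renormalize.
Degenerate cases raise rather than guess: zero-norm inverses, near-zero
quaternion averages (< 10⁻¹²), empty distance sets, single-subject
leave-one-out, and any plan that would place test-subject frames in a
training set (`LeakageError`).

## Known limitations

* The Euler order, the anthropometric template and configurations B/C/D/F
  are documented conventions or placeholders, not published values.
* The componentwise quaternion average is a first-order approximation to
  the rotation mean; for widely dispersed neighbor sets it is biased
  (mitigated by distance weighting, which concentrates mass on close
  neighbors).
* Error accumulation makes distal joints (hands, feet) dominate position
  error; averaged summaries hide this, so per-joint tables are always
  reported alongside.
* The ANN stall rule can stop training in a poor local basin on hard
  tasks; the cross-validation harness, not the stopping rule, is the
  intended guard against undertrained models.
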