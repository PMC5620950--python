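# Methods

This note documents the models, conventions and numerical choices behind
`fallwatch`, and what the synthetic protocol does and does not demonstrate.

## Orientation model

The attitude of a body segment is tracked as a unit quaternion
`q = (q_w, q_x, q_y, q_z)` mapping world-frame vectors to the body frame
(`v_body = R(q) v_world`), with the world z axis up, so a level stationary
accelerometer reads `(0, 0, 1)` g. Gyroscope kinematics use the passive
update `q ← exp(−ω·dt/2) ⊗ q` with `ω` the body angular rate; under the
Euler readout below, a positive body z rate integrates to positive yaw.

The estimator is a quaternion complementary filter: gyro prediction plus two
proportional corrections per sample,

* **gravity (tilt) correction** — the minimal rotation taking the predicted
  body-frame gravity direction toward the measured acceleration direction,
  scaled by `accel_gain` (default 0.02/sample at 100 Hz, i.e. a ~0.5 s time
  constant). Applied in the body frame; it cannot change heading. Samples
  with acceleration norm below 0.3 g (the weightless start phase of a fall)
  skip this step — gravity direction is unobservable in free fall.
* **heading correction** — the measured magnetic field is rotated into the
  world frame, its horizontal heading compared to the reference field's, and
  the state rotated about the *world* z axis by `mag_gain` (default
  0.01/sample) of the error. It cannot change the gravity direction.

With these defaults a 0.5°/s gyro bias settles at a steady-state tilt error
of roughly bias/(gain·rate) ≈ 0.25°, versus ≈ 30° of accumulated drift after
60 s of pure integration — the reason the corrections exist. The filter is a
deliberately simple stand-in behind a small interface: the detector consumes
only Euler angles, and the tests constrain the estimator's *contract*
(gravity/heading consistency, bounded drift), not its internals, so a full
EKF could be substituted without touching anything downstream.

The initial attitude is solved algebraically (TRIAD) from the first sample's
accelerometer + magnetometer pair; identity initialisation would corrupt the
first seconds of every trace. Reference vectors default to gravity `(0,0,1)` g
and a magnetic field `(22, 0, −42)` µT (horizontal north plus downward
inclination, a mid-latitude field). Hard/soft-iron calibration and online
gyro-bias estimation are out of scope.

## Euler readout and its quirk

Angles are extracted with the component formulas

```
yaw   = atan2(2 qx qy − 2 qw qz, 2 qw² + 2 qx² − 1)
pitch = arcsin(2 qw qy − 2 qx qz)
roll  = atan2(2 qy qz − 2 qw qx, 2 qw² + 2 qz² − 1)
```

exactly as stated in the fall-detection literature this package models. The
triple is *mixed*: the pitch line is the standard Hamilton ZYX extraction of
`q`, while the yaw and roll lines are the extraction of the conjugate of
`q`. Taken together the three lines are not the Euler decomposition of any
single rotation convention (an exhaustive numerical search over elemental
composition orders, angle signs and signed-permutation frame changes finds
no match), and the map has no global inverse.

Practical consequences, all verified by tests:

* each single-axis family is inverted exactly by
  `euler_to_quaternion(y, p, r) = q_z(−y) ⊗ q_y(p) ⊗ q_x(−r)`;
* the pitch channel of that composition is recovered exactly for arbitrary
  mixed angles (the pitch line is convention-consistent);
* in the dominant-single-axis regime of human falls — one channel driven
  toward ±90° with a few degrees of noise on the others — the dominant
  channel reads out exactly (pitch) or to a fraction of a degree (roll),
  which is what the detector's `max(|roll|, |pitch|)` consumes;
* for genuinely three-dimensional large-angle rotations the yaw/roll
  channels deviate from any composition's angles; a global 1e−9 matrix
  round-trip is mathematically unattainable with this readout and is not
  claimed.

The conversion itself is validated to 1e−9 degrees against an independent
oracle that evaluates the same component combinations through a
scipy-constructed rotation matrix. The arcsine argument is clamped to
[−1, 1] so rounding noise at the gimbal point yields pitch of exactly ±90°.

## Detector

Thresholds: `a_ti = 2.3` g (impact), `o_tp = 50°` (posture), `t_tp = 2` s
(window). Both comparisons are strict (`>`); at float granularity the
distinction from `≥` is immaterial but must be fixed for exact tests. An
impact is a *crossing* (previous sample at or below, current above), so a
plateau opens one candidate; a trace that begins above threshold counts as a
crossing at sample 0. The posture window is half-open
`(impact, impact + t_tp·rate]` — the impact sample itself is not eligible —
and a window truncated by the end of the recording is evaluated on the
available samples (a fall just before recording ends still alarms if the
angle condition is already met). Posture uses absolute angles with no
baseline subtraction, so a device mounted far off-vertical would
false-alarm; mounting is delegated to calibration. `o_tp = 0` disables the
angle gate, reducing the system to a pure-accelerometer detector (used by
the ablation tests). The posture condition is a single-sample exceedance —
the literal reading of "exceeds within the window"; no sustained-duration
requirement is imposed. When both channels exceed the threshold the event
records whichever attains the larger absolute value.

**One open candidate at a time.** While a posture window is open, later RMS
crossings are absorbed into the current candidate instead of opening new
ones: an elastic landing surface makes the body bounce, and the bounce
echoes would otherwise raise duplicate alarms for one fall. A consequence
found by random testing: strict event-count monotonicity in `a_ti` holds
per impact episode but not for arbitrary multi-spike traces, because
raising `a_ti` can remove an early non-alarming candidate whose blocking
window had swallowed two later spikes. Monotonicity in `o_tp` is
unconditional (impact candidates do not depend on it). The property tests
are scoped accordingly; the protocol's one-activity-per-recording regime is
always in the monotone case.

The streaming detector keeps O(1) state (previous RMS plus the open-window
accumulator) and emits the alarm at the confirming sample; its decisions
are exactly equal to the batch scan, which is asserted on randomized traces.
`peak_rms` and `max_angle` of an event cover impact through alarm (the
quantities knowable at emission time).

## Synthetic protocol

The generator emulates the validation protocol the detector was designed
for: 16 activities (7 falls: backward ending lying / on the elbows /
sitting back up after 2 s; forward ending lying / on the knees; lateral
left / right; 9 ADLs: walking, bending over, taking stairs, sitting on a
chair, sitting and lying on a mattress, stretching, staggering forward /
backward, twisting the waist) on three placements, several repetitions
each, seeded per (activity, segment, repetition) via `SeedSequence` so the
whole set is reproducible from one base seed.

Fall traces: 2 s quiet baseline (RMS 1 ± 0.05 g, angles ~0 ± 2°); a
weightless dip to 0.3 g over 0.4 s; a 0.15 s half-sine impact with peak
drawn from U(2.5, 6.0) g and two bounce echoes at 40% and 15% of the peak;
then a lying posture with the direction channel (pitch for
forward/backward, roll for lateral; sign encodes direction) settled at
U(70°, 90°) — U(60°, 80°) for the elbow variant — for the rest of the
trace. The sitting-up variant returns to 25° after 2 s of lying, which
still alarms because the threshold is crossed inside the posture window.
All magnitudes are calibration choices consistent with the qualitative
signal shapes of the modelled study; none is claimed as a measured value.

ADL traces follow per-activity templates (periodic loading for gait, a
single soft bump for sitting or staggering, slow angle excursions for
bending or lying down) scaled per segment (foot 1.25×, shoulder 1×, waist
0.75×) and hard-capped at 2.25 g / 47° so the non-signature support stays
strictly clear of the thresholds — the modelled study observed zero waist
false alarms, so waist ADLs must never trigger. Problematic
activity/segment pairs carry a *false-positive signature* (an impact-like
spike plus an angle excursion to U(55°, 75°)) with calibrated
probabilities: shoulder bending-over and staggering-forward 0.4 (expected
correct rate 60%), foot walking 0.933 (6.7%), foot stairs 1.0 (0%). These
probabilities are inputs tuned to the reference per-activity rates, not
findings. A separate jump-like spec (RMS spike ~3 g, angles < 25°) exercises
the pure-accelerometer failure mode.

`synthesize_raw` inverts a derived trace into a consistent 9-DOF stream:
the Euler trajectory becomes a quaternion trajectory (sign-continuous), the
accelerometer is the body-frame gravity direction scaled to the trace RMS
plus N(0, 0.01 g) noise, the gyro is the finite-difference body rate plus
N(0, 0.2°/s), the magnetometer the body-frame reference field plus
N(0, 0.5 µT). Passing the stream back through the orientation estimator
recovers the dominant final angle within 5° (tested), closing the loop
between the simulator and the estimator.

What passing tests show — and don't. The simulator reproduces threshold
*morphology* (phase structure, crossing margins, placement-specific failure
modes), not biomechanics: no subject-to-subject variation, no soft-tissue
artefacts, no real gait dynamics, no elderly-vs-young differences. Perfect
simulated sensitivity therefore demonstrates that the implementation makes
the intended decisions under the modelled conditions, not that a deployed
device achieves these rates on real wearers.

## Evaluation

One trial = one trace = one outcome. TP: fall trial with ≥ 1 alarm
(multiple alarms in one fall still count once); FN: fall with none; FP: ADL
with any alarm; TN: ADL with none. Per-activity correct rate =
100·(TP+TN)/n, reported to one decimal. Per placement, sensitivity =
100·TP/(TP+FN), specificity = 100·TN/(TN+FP), accuracy = 100·(TP+TN)/total,
computed from pooled counts; under the balanced protocol (equal trials per
activity) specificity equals the unweighted mean of per-ADL rates and
accuracy = (7·sensitivity + 9·specificity)/16, which the tests cross-check.
`trials_from_rates` reconstructs balanced-count outcomes from a printed
per-activity rate table (45 trials per activity, the reference protocol's
15 subjects × 3 repetitions), letting the aggregation be verified against
the published per-placement numbers exactly.

## Problem sizes and numerics

The acceptance script simulates 50 repetitions per fall subcategory per
placement (1050 trials, a few seconds of compute); the test suite uses
2–50 repetitions per check. Traces are 6 s at 100 Hz. Text I/O writes
floats with `%.17g` and parses with numpy's round-trip-precise reader, so
read-after-write is bit-exact. Timestamps are validated strictly increasing
with spacing within 1% of 1/rate. Quaternions are renormalized after every
update; the zero quaternion is rejected.
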