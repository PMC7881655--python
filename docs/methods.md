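# Methods

This note records the models and procedures `myogym` implements, the
defaults it chose where the design was open, and what its synthetic test
bed does and does not establish.

## Signal model and features

EMG is treated as an 8-channel sampled series at a configurable rate,
default fs = 1000 Hz. The default is a standard choice for surface EMG and
makes the canonical window (128 ms) and step (50 ms) integral sample
counts; non-integral conversions are an error rather than a silent
rounding. Windowing follows the closed form `floor((N − W)/S) + 1`; a
recording shorter than one window produces an empty sequence and a
warning.

Per window and channel the four Hudgins time-domain features are computed:

- MAV = mean |x_i|
- ZC  = #{i : x_i·x_{i+1} < 0 and |x_i − x_{i+1}| ≥ θ_zc}
- WL  = Σ |x_{i+1} − x_i|
- SSC = #{i : (x_i − x_{i−1})(x_i − x_{i+1}) > θ_ssc}

Both deadband thresholds default to 0 (the signal chain being modelled
pre-conditions the EMG); they are exposed in the feature config. The
32-vector layout is channel-major `(MAV, ZC, WL, SSC) × channels 1–8` and
is frozen, since serialized models depend on it.

Z-normalization statistics (per-dimension mean and SD over the training
windows) are estimated once at fit time and stored with the model; they
are never re-estimated at inference. The SD is floored at ε = 1e−8 so a
constant dimension maps to 0 rather than exploding. Whether such
statistics should be per-training-event or persisted across sessions is an
open protocol question; freezing at fit time is the conservative choice
and is what the serialization format encodes.

## Regressor and targets

Architecture is fixed at 32 → 50 → 25 → n_outputs with tanh after each
hidden layer and a linear output; n_outputs equals the number of currently
trained movements (≤ 7). Training is MSE with Adam, mini-batches of 64
windows, early stopping on a randomly chosen 10% validation split, with
config-exposed patience 10, epoch budget 500 and learning rate 1e−3
(the recipe fixes batch size and split; the rest are this package's
defaults). Fitting is delegated to scikit-learn's `MLPRegressor`, which
restores the best-validation-epoch weights; the weights are then copied
into a plain JSON-serializable container and inference is an explicit
forward pass, so loading a model needs no trainer state. Training is
bit-reproducible given the seed, which is mandatory.

Regression targets are built from the trapezoid reference trace: for each
window, the reference value (fraction of MVC) at the window's final sample
on the prompted movement's output and 0 elsewhere; rest recordings target
the zero vector. This gives the "strength ≈ fraction of MVC" semantics
that proportional control and the force biofeedback assume. Negative raw
outputs are rectified to zero at prediction time; nonnegativity is a
contract of the strength vector and rectification is the simplest
mechanism that honours it.

## Command mapping and streaming

Sign conventions (not dictated by the math, fixed here and documented):
fine pinch +, lateral pinch −; CW +, CCW −; flexion +, extension −; hand
open is the fourth, nonnegative slot. The gain from strength to command
defaults to 100, i.e. strength 1.0 (MVC) saturates the ±100 command range.
Pinch/open conflicts discard the smaller magnitude; on an exact tie the
open element is discarded (grips are the training focus; the tie rule is
arbitrary and isolated in `resolve_conflict`). The conflict rule is
idempotent and every emitted command lies in [−100, +100].

The 4-tap moving-average post-filter starts from a zero-filled buffer and
always divides by 4, so a step input produces 25/50/75/100 on successive
emissions: early output is attenuated rather than delayed, which is the
behaviour wanted at control onset. Streaming emits one smoothed command
per step; the reported algorithmic delay is window + step (178 ms at
128/50 ms), consistent with a 20 Hz command rate.

## Protocols

The trapezoid reference ramps 0 → level → level → 0 with a 5 s plateau at
30/60/90% MVC. Ramp duration is unstated upstream; 1 s per side is the
default and is configurable. Force biofeedback uses an MVC-relative MAV
ratio: `sum_c MAV_c(window) / sum_c MAV_c(MVC)`, clipped to [0, 1.2],
against the prompted movement's MVC profile (an MVC baseline is recorded
per movement). The summed (MVC-weighted) form rather than an unweighted
per-channel mean is deliberate: with spatially focal activation patterns
an unweighted mean is dominated by near-silent channels whose ratio is
noise-over-noise; the weighted form is monotone in global amplitude and
equals 1 at MVC amplitude by construction.

Training-set selection takes the most recent five recording procedures
(all if fewer exist) and warns when the selection does not span the three
arm postures (hanging, armrest, reaching). It is a pure function of the
ordered history.

Motion Test: three trials per trained movement, one per level, margins
{30%: ±15, 60%: ±20, 90%: ±30} percentage points of MVC. A trial succeeds
when the in-criterion time — model argmax equals the prompt *and* the
force estimate is inside the band — reaches 2 s before the 6 s window
elapses. "Two seconds" is read as cumulative time; a consecutive-dwell
variant is available via `cumulative=False`. Success times are therefore
in [2 s, 6 s] and failures report 6 s. The trial clock starts at prompt
onset (stream start).

## Game engines

Both engines are pure state machines (`step(state, input, dt) → (state,
events)`), so trajectories replay exactly. Constants that are rules of the
games: grip activation at a pinch command of ±25 (sign matching the
dispenser colour: blue = fine pinch +, red = lateral pinch −) with every
other DoF at ≤ 24; a 10 s activation timeout; an aperture cap of 1.7
object widths; sparks strictly above 1.5 widths; a forced close at the
cap ("fully opened" is read as reaching the cap); 1000 points per
release. MyoBox plays from raw channel RMS through the fixed linear
triplet mapping — deliberately not through the regressor — while the
gripper plays from the regressor's command vector, mirroring the
two-stage training design.

Everything else is engine configuration with documented defaults, echoed
into every episode log: MyoBox arena 200 × 100 units, ball gain 60
units/s, platform 80 → 20 units in steps of 10 per level-up, three boxes
per level on a deterministic row; gripper light speed 20 units/s, avatar
gain 40 units/s, beam/lose distances 15/40 units, ±10/−5 points per
second, 1 s dwell to dispense, open/close rates 1.0/2.0 widths/s at full
command, and a fragile-break threshold of 1.0 widths/s closing speed
(so fragile objects need |pinch| < 50 to close safely). These are play-
scale choices, not measured quantities.

## Pattern metrics

The separability/consistency formulas are defined here as centroid
statistics in the normalized feature space: per-class mean distance to the
class centroid (WD; mean over classes), per-class centroid distance to the
nearest other centroid (IDNN) and the mean over all other centroids
(IDAN), each averaged over classes; IDNN ≤ IDAN by construction. The
upstream formulation defers its exact formulas to an appendix that is not
part of the available text, so the distance is pluggable (Euclidean
default, pooled-covariance Mahalanobis option) rather than asserted as
ground truth. Session values are means over the session's recording
procedures; metrics are computed on graded trials only (not MVC, not
rest).

## Synthetic EMG

The generator emulates the recording protocol's *inputs*: channel c of a
trial is `pattern[m, c] · envelope(t) · carrier_c(t) + noise · n_c(t)`,
with the trapezoid as envelope, independent per-channel Gaussian carriers
band-passed to 20–450 Hz (the usual surface-EMG band) and normalized to
unit RMS, and white baseline noise. Plateau RMS of a channel is therefore
`pattern · level` up to noise, so amplitude ratios across levels and
channels are exact test oracles. Patterns interpolate between one-hot
rows (overlap 0, orthogonal) and identical rows (overlap 1). Defaults —
overlap 0.2, noise 0.05, amplitude jitter 0.1 — describe a cooperative
subject with moderately distinct movements; parameter-recovery checks use
the separable condition (overlap 0, noise 0.02, jitter 0) that such
checks presuppose. Sessions are one MVC plus three graded trials per
movement per procedure, postures cycling hanging → armrest → reaching,
reproducible from a single integer seed.

What this does **not** model: motor-unit physiology, electrode shift,
fatigue, crosstalk structure, postural EMG changes (posture is a label
only) or amputation-specific signal changes. Passing tests on this bed
show the pipeline's mechanics and learnability under controlled
conditions; they say nothing about human performance.

## Problem sizes and numerics

Test and example runs use 2–3 procedures of 2–7 movements (7 s trials at
1 kHz → ~138 windows each; a full 7-movement, 3-procedure session is
~11.5k windows), which trains in seconds while leaving thousands of
held-out plateau windows for accuracy checks. Degenerate inputs are
errors, not guesses: sub-window recordings warn and return nothing,
single-sample channels and empty classes raise, zero MVC references
raise, non-integral window/step conversions raise naming the sampling
rate. Determinism everywhere comes from explicit integer seeds; nothing
is derived from the wall clock.

## Known limitations

- The regressor's epoch budget/patience/learning rate are defaults, not
  reproductions; different values change convergence speed, not the
  contract.
- The "open as the fourth command element" reading (with pinch/open
  mutual exclusion) is one of two possible readings of the 7 → 4
  conversion; the alternative (open folded into the grip axis) is noted
  but not implemented.
- Game scoring beyond the printed 1000-point release award is
  package-defined.
- The Mahalanobis metric variant uses a pooled covariance with a
  pseudo-inverse; with few windows per class it is poorly conditioned and
  the Euclidean default is preferred.
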