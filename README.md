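# myogym

Proportional, simultaneous myoelectric prosthesis control — and the
serious-game instruments used to train it — as a tested, hardware-free
Python library.

Pattern-recognition prosthesis control maps multi-channel surface EMG to
movement commands through a learned model instead of the clinical two-site
direct-control scheme. Training such control needs instruments: graded
force-tracking recordings, a screen-based Motion Test, biofeedback games,
and metrics that quantify how consistent and separable a user's EMG
patterns are. `myogym` implements that whole stack so researchers can
prototype, test and simulate it on synthetic EMG:

- **Features** — 8-channel EMG cut into overlapping 128 ms windows with a
  50 ms step (20 Hz command cadence, < 200 ms delay); per channel the
  Hudgins time-domain set MAV, ZC, WL, SSC; z-normalization frozen at fit
  time.
- **Regressor** — a feed-forward network (32 → 50 → 25 → n movements, tanh
  hidden layers, linear output) trained with Adam on an MSE loss,
  mini-batches of 64 windows and early stopping on a random 10% validation
  split; outputs one nonnegative strength per movement (fine pinch, lateral
  pinch, wrist rotation CW/CCW, wrist flexion/extension, hand open).
- **Control mapping** — strengths folded into four signed DoF commands in
  [−100, +100] (opposing movements share an axis with opposite signs);
  when pinch and open conflict the smaller magnitude is discarded; a 4-tap
  moving average smooths the 20 Hz stream.
- **Protocols** — trapezoidal force references (ramp–5 s plateau–ramp at
  30/60/90% MVC), MVC-relative force estimation, the "train on the most
  recent five recording procedures" rule with a three-posture coverage
  check, and the Motion Test (hold the prompted movement at the prompted
  force, margins 15/20/30 percentage points, for 2 s within a 6 s window;
  three trials per trained movement).
- **Games** — headless deterministic engines for *MyoBox* (ball steered by
  a fixed antagonistic-triplet mapping of per-electrode RMS, platforms that
  narrow as levels advance) and *Prosthesis Gripper* (light tracking, grip
  activation at ±25 with all other DoFs ≤ 24 within 10 s, aperture capped
  at 1.7 object widths with sparks above 1.5 and a forced close at the cap,
  fragile objects, 1000-point release).
- **Metrics** — within-class distance (WD, consistency) and inter-class
  distances to the nearest/all other class centroids (IDNN/IDAN,
  separability), plus the per-channel RMS "spider" profile used for
  coaching.
- **Synthetic EMG** — a seedable generator of trapezoid-modulated,
  movement-specific 8-channel recordings with dials for pattern overlap,
  noise and amplitude jitter; it writes the same CSV + JSON-sidecar format
  the rest of the package reads.

## Worked example

```python
import numpy as np
import myogym
from myogym.regressor import TrainConfig

movements = ["fine_pinch", "hand_open", "wrist_rotation_cw", "wrist_rotation_ccw"]
params = myogym.GeneratorParams(seed=11, overlap=0.0, noise=0.02,
                                amplitude_jitter=0.0)
session = myogym.generate_session(params, movements, n_procedures=3)
selected = myogym.select_training_data(session)          # last-five rule
recordings = [r for p in selected for r in p.recordings]
model = myogym.train_from_recordings(recordings, movements, TrainConfig(seed=5))

rec = myogym.generate_recording("hand_open", 0.6, params, seed=99)
result = myogym.run_stream(model, rec)
print(result.commands.shape[0], result.cadence_hz, result.delay_ms)
print(np.round(result.commands[40:100].mean(axis=0), 1))
```

prints

```
138 20.0 178.0
[ 0.   0.3  0.  62.5]
```

i.e. a 7 s trial yields 138 commands at 20 Hz with a 178 ms algorithmic
delay, and on the 60%-MVC plateau the smoothed command sits near +62 on
the hand-open DoF (proportional control: strength ≈ fraction of MVC,
scaled to ±100) while the other three DoFs stay near zero. The scripts in
`examples/` walk through each capability (session generation, metrics,
training/streaming, the Motion Test, both games) and print the numbers
they compute.

A thin CLI mirrors the workflow
(`myogym generate | train | stream | motion-test | myobox | gripper |
metrics`); run `myogym --help`.

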