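"""Run a simulated Motion Test against a trained model.

Each trained movement gets three trials (30/60/90% MVC with force margins
of 15/20/30 percentage points); a trial succeeds when the model's argmax
matches the prompt at the right force for a cumulative two seconds inside
a six-second window.
"""

import numpy as np

import myogym
from myogym.regressor import TrainConfig

movements = ["fine_pinch", "hand_open"]
params = myogym.GeneratorParams(seed=13, overlap=0.0, noise=0.02,
                                amplitude_jitter=0.0)
session = myogym.generate_session(params, movements, n_procedures=3)
model = myogym.train_from_recordings(
    [r for p in session for r in p.recordings], movements,
    TrainConfig(seed=2),
)

rng = np.random.default_rng(17)
trials = myogym.motion_test(
    model, lambda m, lvl: myogym.generate_recording(m, lvl, params, rng=rng)
)
for t in trials:
    print(f"{t.movement:12s} level={t.level:.0%} margin=+-{t.margin:.0%} "
          f"-> {'success' if t.success else 'failure'} at t={t.time_s:.2f} s")
# success times near 3 s: the 2 s criterion accumulates once the 1 s ramp
# reaches the force band.
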