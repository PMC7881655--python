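"""Train the strength regressor and stream 20 Hz prosthesis commands.

The model maps 32 normalized Hudgins features to one nonnegative strength
per movement; streaming folds strengths into signed 4-DoF commands in
[-100, 100], smooths them with a 4-tap moving average and emits one command
per 50 ms step (178 ms algorithmic delay for 128 ms windows).
"""

import numpy as np

import myogym
from myogym.regressor import TrainConfig

movements = ["fine_pinch", "hand_open", "wrist_rotation_cw",
             "wrist_rotation_ccw"]
params = myogym.GeneratorParams(seed=11, overlap=0.0, noise=0.02,
                                amplitude_jitter=0.0)
session = myogym.generate_session(params, movements, n_procedures=3)

selected = myogym.select_training_data(session)  # the last-five rule
recordings = [r for p in selected for r in p.recordings]
model = myogym.train_from_recordings(recordings, movements,
                                     TrainConfig(seed=5))
print(f"trained for {len(model.loss_curve_)} epochs on "
      f"{len(recordings)} recordings")

rec = myogym.generate_recording("hand_open", 0.6, params, seed=99)
result = myogym.run_stream(model, rec)
print(f"{result.commands.shape[0]} commands at {result.cadence_hz:.0f} Hz, "
      f"delay {result.delay_ms:.0f} ms")
plateau = result.commands[40:100]  # the trapezoid's 60%-MVC plateau
print("mean plateau command (pinch, rotation, flex_ext, open):",
      np.round(plateau.mean(axis=0), 1))
# the open DoF should sit near +60 (0.6 MVC x scale 100), others near 0.
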