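"""Play both serious-game engines headlessly.

MyoBox steers a ball from raw per-electrode RMS values (the fixed
antagonistic-triplet mapping); Prosthesis Gripper runs its
tracking -> dispense -> grasp -> release loop from 4-DoF command vectors.
"""

import numpy as np

from myogym.games import (
    GripperConfig,
    avatar_direction,
    gripper_initial_state,
    gripper_step,
    myobox_initial_state,
    myobox_step,
)

# --- MyoBox: activate the 2-3-4 electrode triplet to fly up to the boxes
state = myobox_initial_state()
for _ in range(20):
    d = avatar_direction([0, 1, 1, 1, 0, 0, 0, 0])  # straight up
    state, events = myobox_step(state, d, dt=0.05)
    for e in events:
        print("myobox event:", e)
print(f"myobox: ball at ({state.x:.1f}, {state.y:.1f}), "
      f"score={state.score}, level={state.level}")

# --- Gripper: track the light, activate fine pinch, grasp and release
cfg = GripperConfig()
g = gripper_initial_state(cfg)
log = []
opened = False  # latch: open past the object's width once, then close
for step in range(2000):
    if g.phase == "tracking":
        cmd = [0, 100 * g.light_target, 0, 0]   # chase the light
    elif g.phase == "dispense":
        cmd = [30, 0, 0, 0]                     # fine pinch at 30 (>= 25)
    elif g.phase == "grasp":
        opened = opened or g.aperture >= 1.2 * g.object.width
        cmd = [40, 0, 0, 0] if opened else [0, 0, 0, 80]  # close gently
    else:  # release
        cmd = [0, 0, 0, 60]
    g, events = gripper_step(g, cmd, cfg, dt=0.05)
    log.extend(events)
    if "released" in events:
        break
print("gripper events:", " -> ".join(log))
print(f"gripper: finished in {step + 1} ticks with score {g.score:.0f}")
# one full loop ends with the 1000-point release award.
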