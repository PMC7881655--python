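"""Generate a synthetic EMG recording session and inspect its structure.

Each procedure records, per movement, an MVC baseline plus one
trapezoid-tracked trial at 30/60/90% MVC, in one of three arm postures.
"""

import numpy as np

import myogym

params = myogym.GeneratorParams(seed=7)
session = myogym.generate_session(
    params, ["fine_pinch", "hand_open"], n_procedures=3
)

for proc in session:
    mvc = sum(r.level == 1.0 for r in proc.recordings)
    graded = sum(0 < r.level < 1.0 for r in proc.recordings)
    print(f"procedure {proc.index}: posture={proc.posture:8s} "
          f"MVC trials={mvc} graded trials={graded}")

rec = session[0].recordings[1]  # fine pinch at 30% MVC
rms = np.sqrt(np.mean(rec.signal**2, axis=0))
print(f"\nfirst graded trial: {rec.movement} at {rec.level:.0%} MVC, "
      f"{rec.duration_ms:.0f} ms at {rec.fs:.0f} Hz")
print("whole-trial channel RMS:", np.round(rms, 3))
# channel 1 carries fine pinch; the trapezoid envelope dilutes the plateau
# amplitude (0.3 * pattern weight) over ramps, so RMS ~ 0.2 there.
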