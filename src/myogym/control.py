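"""From movement strengths to smoothed 4-DoF prosthesis commands.

The seven nonnegative movement strengths are folded into four signed
degree-of-freedom commands in [-100, +100]: opposing movements share one
axis with opposite signs (fine pinch +/lateral pinch -, wrist rotation
CW +/CCW -, flexion +/extension -) and hand open occupies the fourth slot.
Because a hand cannot close into a pinch and open simultaneously, when both
the pinch and open elements are nonzero the one with the smaller absolute
value is discarded. A 4-tap moving-average filter smooths the command
stream, which is emitted at the windowing cadence (20 Hz for a 50 ms step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as ft
from .recording import EmgRecording
from .regressor import EmgRegressor, full_strengths

#: Command slots, in storage order.
DOF_NAMES = ("pinch", "rotation", "flex_ext", "open")

COMMAND_LIMIT = 100.0


def resolve_conflict(cmd: np.ndarray) -> np.ndarray:
    """Zero the smaller of pinch/open when both are active.

    Ties discard the open element (grips take precedence). Idempotent.
    """
    cmd = np.array(cmd, dtype=float)
    pinch, open_ = cmd[0], cmd[3]
    if pinch != 0.0 and open_ != 0.0:
        if abs(open_) <= abs(pinch):
            cmd[3] = 0.0
        else:
            cmd[0] = 0.0
    return cmd


def combine_dofs(strengths: np.ndarray, scale: float = 100.0) -> np.ndarray:
    """Fold 7 movement strengths into the raw 4-DoF signed command vector.

    Each opposing pair is differenced, scaled, and clamped to [-100, +100];
    the pinch/open mutual-exclusion rule is then applied.
    """
    s = np.asarray(strengths, dtype=float)
    if s.shape != (7,):
        raise ValueError(f"expected 7 movement strengths, got shape {s.shape}")
    if not np.all(np.isfinite(s)):
        raise ValueError("movement strengths must be finite")
    raw = np.array(
        [
            scale * (s[0] - s[1]),  # fine pinch (+) vs lateral pinch (-)
            scale * (s[2] - s[3]),  # wrist rotation CW (+) vs CCW (-)
            scale * (s[4] - s[5]),  # wrist flexion (+) vs extension (-)
            scale * s[6],           # hand open
        ]
    )
    raw = np.clip(raw, -COMMAND_LIMIT, COMMAND_LIMIT)
    return resolve_conflict(raw)


class MovingAverageFilter:
    """Moving average over the last ``taps`` raw command vectors.

    The buffer starts zero-filled, so early emissions are attenuated rather
    than delayed: a step from 0 to 100 produces 25, 50, 75, 100. Linear,
    shift-invariant, DC gain 1 once the buffer has filled.
    """

    def __init__(self, taps: int = 4, n_dofs: int = 4):
        if taps < 1:
            raise ValueError("taps must be >= 1")
        self.taps = taps
        self._buffer = np.zeros((taps, n_dofs))
        self._i = 0

    def update(self, cmd: np.ndarray) -> np.ndarray:
        self._buffer[self._i % self.taps] = np.asarray(cmd, float)
        self._i += 1
        return self._buffer.mean(axis=0)

    __call__ = update


@dataclass
class StreamResult:
    """Timed command stream produced by :func:`run_stream`.

    ``delay_ms`` is the algorithmic latency: one full window plus one step
    (178 ms for the default 128/50 ms configuration).
    """

    t_ms: np.ndarray
    commands: np.ndarray
    raw_commands: np.ndarray
    cadence_hz: float
    delay_ms: float
    events: list[str] = field(default_factory=list)


def run_stream(
    model: EmgRegressor,
    recording: EmgRecording,
    scale: float = 100.0,
    taps: int = 4,
) -> StreamResult:
    """Slide the model over a recording, emitting one smoothed command per
    step (20 Hz at the default 50 ms step)."""
    fc = model.feature_config
    windows = ft.segment_windows(recording, fc.window_ms, fc.step_ms)
    filt = MovingAverageFilter(taps=taps)
    t, raws, outs = [], [], []
    for win in windows:
        strengths = model.strengths_from_window(win)
        raw = combine_dofs(full_strengths(strengths, model.movements), scale)
        outs.append(filt(raw))
        raws.append(raw)
        t.append(win.start_ms + fc.window_ms)
    events = [] if windows else ["source underrun: no complete window"]
    return StreamResult(
        t_ms=np.asarray(t),
        commands=np.asarray(outs).reshape(len(outs), 4),
        raw_commands=np.asarray(raws).reshape(len(raws), 4),
        cadence_hz=1000.0 / fc.step_ms,
        delay_ms=fc.window_ms + fc.step_ms,
        events=events,
    )
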