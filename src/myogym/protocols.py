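"""Recording and assessment protocols around the regression pipeline.

Covers the trapezoidal force-tracking reference used to elicit graded
contractions, the MVC-relative force estimate shown as biofeedback, the
"train on the most recent five procedures" data-selection rule with its
three-posture coverage check, and the Motion Test: a screen-based trial
procedure where the prompted movement must be held at the prompted force
level for two seconds within a six-second window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from . import features as ft
from .recording import LEVELS, EmgRecording, Procedure
from .regressor import EmgRegressor, FeatureConfig

#: Accepted force-band half-widths per target level, fractions of MVC
#: (printed as 15, 20 and 30 percentage points).
MARGINS: dict[float, float] = {0.3: 0.15, 0.6: 0.20, 0.9: 0.30}

HOLD_S = 2.0
TRIAL_WINDOW_S = 6.0


def trapezoid(
    level: float,
    plateau_s: float = 5.0,
    ramp_s: float = 1.0,
    fs: float = 1000.0,
    pre_s: float = 0.0,
    post_s: float = 0.0,
) -> np.ndarray:
    """Sampled ramp--plateau--ramp force reference peaking at ``level``.

    ``level`` is a fraction of MVC in [0, 1]; level 0 returns an all-zero
    series of the same duration (the rest template).
    """
    if ramp_s <= 0:
        raise ValueError("ramp duration must be positive")
    if not 0 <= level <= 1:
        raise ValueError(f"level must be in [0, 1], got {level}")
    t = np.arange(round((pre_s + ramp_s + plateau_s + ramp_s + post_s) * fs)) / fs
    up_end = pre_s + ramp_s
    down_start = up_end + plateau_s
    down_end = down_start + ramp_s
    ref = np.interp(
        t, [0.0, pre_s, up_end, down_start, down_end, down_end + post_s],
        [0.0, 0.0, level, level, 0.0, 0.0],
    )
    return ref


def estimate_force(
    window: ft.Window | np.ndarray, mvc_mav: np.ndarray
) -> float:
    """Contraction intensity as a fraction of MVC, from one EMG window.

    The estimate is the MVC-weighted mean of per-channel MAV ratios,
    i.e. ``sum(MAV(window)) / sum(MAV(MVC))`` against the prompted
    movement's MVC profile, clipped to [0, 1.2]. Monotone in global signal
    amplitude; exactly the self-ratio 1.0 when the window matches the MVC
    amplitude.
    """
    mvc_mav = np.asarray(mvc_mav, float)
    if np.any(mvc_mav < 0) or mvc_mav.sum() <= 0:
        raise ValueError("MVC MAV reference must be nonnegative with a "
                         "positive total")
    x = window.samples if isinstance(window, ft.Window) else np.asarray(window, float)
    mav = np.mean(np.abs(x), axis=0)
    return float(np.clip(mav.sum() / mvc_mav.sum(), 0.0, 1.2))


def mvc_mav_profiles(
    recordings: Iterable[EmgRecording],
    feature_config: FeatureConfig | None = None,
) -> dict[str, np.ndarray]:
    """Per-movement 8-channel MAV profiles from MVC trials (level 1.0),
    averaged over their plateau windows and over repeats."""
    fc = feature_config or FeatureConfig()
    sums: dict[str, list[np.ndarray]] = {}
    for rec in recordings:
        if rec.level != 1.0:
            continue
        for win in ft.plateau_windows(rec, fc.window_ms, fc.step_ms):
            sums.setdefault(rec.movement, []).append(
                np.mean(np.abs(win.samples), axis=0)
            )
    return {m: np.mean(v, axis=0) for m, v in sums.items()}


def select_training_data(history: Sequence[Procedure]) -> list[Procedure]:
    """The most recent five recording procedures (all, if fewer exist).

    Pure function of the ordered history. Warns when the selection does not
    cover all three arm postures, which the protocol requires.
    """
    if len(history) == 0:
        raise ValueError("recording history is empty; nothing to train on")
    selection = list(history[-5:])
    postures = {p.posture for p in selection}
    missing = {"hanging", "armrest", "reaching"} - postures
    if missing:
        warnings.warn(
            "selected procedures do not cover all postures; missing: "
            + ", ".join(sorted(missing)),
            stacklevel=2,
        )
    return selection


@dataclass
class MotionTestTrial:
    """Outcome of one Motion Test movement trial."""

    movement: str
    level: float
    margin: float
    success: bool
    time_s: float


def run_trial(
    decisions: Iterable[tuple[str, float]],
    dt: float,
    prompt: str,
    level: float,
    margin: float | None = None,
    hold_s: float = HOLD_S,
    window_s: float = TRIAL_WINDOW_S,
    cumulative: bool = True,
) -> MotionTestTrial:
    """Evaluate one trial against a decision stream.

    ``decisions`` yields per-tick pairs (predicted movement, estimated
    force). A tick is in-criterion when the prediction matches the prompt
    and the force lies within ``margin`` of the target level. The trial
    succeeds once the in-criterion time reaches ``hold_s`` (cumulative by
    default; set ``cumulative=False`` for a consecutive-dwell rule) before
    the window elapses; failures report the full window duration.
    """
    if margin is None:
        margin = MARGINS[level]
    t = 0.0
    held = 0.0
    for movement, force in decisions:
        if t >= window_s - 1e-9:
            break
        t += dt
        in_criterion = movement == prompt and abs(force - level) <= margin + 1e-12
        if in_criterion:
            held += dt
        elif not cumulative:
            held = 0.0
        if held >= hold_s - 1e-9:
            return MotionTestTrial(prompt, level, margin, True, round(t, 9))
    return MotionTestTrial(prompt, level, margin, False, window_s)


def decisions_from_recording(
    model: EmgRegressor,
    recording: EmgRecording,
    mvc_mav: np.ndarray,
) -> list[tuple[str, float]]:
    """Per-window (argmax movement, force estimate) decisions for a trial."""
    fc = model.feature_config
    out = []
    for win in ft.segment_windows(recording, fc.window_ms, fc.step_ms):
        strengths = model.strengths_from_window(win)
        out.append(
            (model.movements[int(np.argmax(strengths))],
             estimate_force(win, mvc_mav))
        )
    return out


def motion_test_from_decisions(
    decision_factory: Callable[[str, float], Iterable[tuple[str, float]]],
    movements: Sequence[str],
    levels: Sequence[float] = LEVELS,
    dt: float = ft.STEP_MS / 1000.0,
    cumulative: bool = True,
) -> list[MotionTestTrial]:
    """Run the full Motion Test grid: three trials (one per level) for each
    trained movement."""
    return [
        run_trial(decision_factory(m, lvl), dt, m, lvl, cumulative=cumulative)
        for m in movements
        for lvl in levels
    ]


def motion_test(
    model: EmgRegressor,
    recording_factory: Callable[[str, float], EmgRecording],
    mvc_mav: Mapping[str, np.ndarray] | None = None,
    levels: Sequence[float] = LEVELS,
    cumulative: bool = True,
) -> list[MotionTestTrial]:
    """Motion Test driven by the model over streamed recordings.

    ``recording_factory(movement, level)`` supplies the EMG for each trial
    (a live source in the clinic; the synthetic generator here). MVC MAV
    profiles default to the ones stored on the model.
    """
    mvc = dict(mvc_mav) if mvc_mav is not None else model.mvc_mav
    missing = [m for m in model.movements if m not in mvc]
    if missing:
        raise ValueError(f"no MVC reference for movement(s): {missing}")

    def decisions(movement: str, level: float):
        return decisions_from_recording(
            model, recording_factory(movement, level), mvc[movement]
        )

    return motion_test_from_decisions(
        decisions,
        model.movements,
        levels,
        dt=model.feature_config.step_ms / 1000.0,
        cumulative=cumulative,
    )
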