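"""Headless, deterministic engines for the two training games.

**MyoBox** trains EMG pattern separability: the player steers a ball from
the raw per-electrode RMS amplitudes through a fixed linear mapping
(antagonistic electrode triplets vote for up/down and left/right), collects
boxes while staying above a platform, and the platform narrows on each
level-up so precision requirements grow.

**Prosthesis Gripper** trains proportional control and grasping from the
regressor's 4-DoF command vector. A tracking phase (follow a moving light
with one DoF) is followed by a dispense phase (activate the grip matching
the dispenser colour: command of at least +/-25 on the pinch axis with every
other DoF at 24 or below, within ten seconds), a grasp phase (open the
gripper around the falling object -- never beyond 1.7 object widths, sparks
warn above 1.5, the cap triggers a forced close -- then close with the
correct grip, gently if the object is fragile) and a release that awards
1000 points.

Both engines are pure state machines: ``step(state, input, dt)`` returns a
new state plus a list of named events, so identical inputs reproduce
identical trajectories. Geometry, gains and point rates that the games need
but that have no single canonical value are explicit config-dataclass
fields, logged into every episode record.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np


class Direction(NamedTuple):
    """Avatar direction in the MyoBox arena (x right, y up)."""

    x: float
    y: float


def avatar_direction(rms: Sequence[float]) -> Direction:
    """Map eight per-electrode RMS values to an avatar direction.

    With electrodes numbered 1..8 around the forearm::

        y = (RMS2 + RMS3 + RMS4)/3 - (RMS6 + RMS7 + RMS8)/3
        x = (RMS1 + RMS2 + RMS8)/3 - (RMS4 + RMS5 + RMS6)/3

    The mapping is linear, so uniform activation cancels to (0, 0).
    """
    r = np.asarray(rms, dtype=float)
    if r.shape != (8,):
        raise ValueError(f"avatar_direction needs 8 RMS values, got {r.shape}")
    y = (r[1] + r[2] + r[3]) / 3.0 - (r[5] + r[6] + r[7]) / 3.0
    x = (r[0] + r[1] + r[7]) / 3.0 - (r[3] + r[4] + r[5]) / 3.0
    return Direction(float(x), float(y))


# ---------------------------------------------------------------------------
# MyoBox
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MyoBoxConfig:
    """Arena geometry and progression constants (arena units are abstract)."""

    gain: float = 60.0            # ball speed per unit direction, units/s
    arena_half_width: float = 100.0
    arena_height: float = 100.0
    platform_width: float = 80.0  # starting platform width
    platform_min_width: float = 20.0
    platform_shrink: float = 10.0  # width decrease per level-up
    box_radius: float = 8.0       # collection distance
    boxes_per_level: int = 3
    box_y: float = 45.0           # altitude of the box row
    points_per_box: int = 100
    ball_start: tuple[float, float] = (0.0, 10.0)


def boxes_for_level(cfg: MyoBoxConfig, platform_width: float) -> tuple[tuple[float, float], ...]:
    """Deterministic box placement: a row spread across the platform."""
    half = platform_width / 2.0 - cfg.box_radius / 2.0
    xs = np.linspace(-half, half, cfg.boxes_per_level)
    return tuple((float(x), cfg.box_y) for x in xs)


@dataclass(frozen=True)
class MyoboxState:
    """Ball position, remaining boxes, score and difficulty level."""

    x: float
    y: float
    platform_width: float
    boxes: tuple[tuple[float, float], ...]
    score: int = 0
    level: int = 1
    falls: int = 0


def myobox_initial_state(cfg: MyoBoxConfig | None = None) -> MyoboxState:
    cfg = cfg or MyoBoxConfig()
    return MyoboxState(
        x=cfg.ball_start[0],
        y=cfg.ball_start[1],
        platform_width=cfg.platform_width,
        boxes=boxes_for_level(cfg, cfg.platform_width),
    )


def myobox_step(
    state: MyoboxState,
    direction: Direction | Sequence[float],
    cfg: MyoBoxConfig | None = None,
    dt: float = 0.05,
) -> tuple[MyoboxState, list[str]]:
    """Advance MyoBox by one tick.

    The ball moves by ``gain * direction * dt``. Leaving the platform's
    horizontal extent resets the ball (a fall, score kept). Touching a box
    collects it; collecting all boxes levels up and narrows the platform
    toward the configured minimum.
    """
    cfg = cfg or MyoBoxConfig()
    dx, dy = float(direction[0]), float(direction[1])
    events: list[str] = []
    x = float(np.clip(state.x + cfg.gain * dx * dt,
                      -cfg.arena_half_width, cfg.arena_half_width))
    y = float(np.clip(state.y + cfg.gain * dy * dt, 0.0, cfg.arena_height))
    score, level, falls = state.score, state.level, state.falls
    width, boxes = state.platform_width, state.boxes

    if abs(x) > width / 2.0:
        events.append("fell_off_platform")
        falls += 1
        x, y = cfg.ball_start
    else:
        remaining = []
        for bx, by in boxes:
            if np.hypot(x - bx, y - by) <= cfg.box_radius:
                events.append("box_collected")
                score += cfg.points_per_box
            else:
                remaining.append((bx, by))
        boxes = tuple(remaining)
        if not boxes:
            level += 1
            new_width = max(cfg.platform_min_width, width - cfg.platform_shrink)
            if new_width < width:
                events.append("level_up:platform_narrowed")
            else:
                events.append("level_up:platform_at_minimum")
            width = new_width
            boxes = boxes_for_level(cfg, width)

    return (
        replace(state, x=x, y=y, platform_width=width, boxes=boxes,
                score=score, level=level, falls=falls),
        events,
    )


# ---------------------------------------------------------------------------
# Prosthesis Gripper
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GripperObject:
    """An object dropped by the dispenser. ``colour`` selects the required
    grip: blue for fine pinch (+), red for lateral pinch (-)."""

    width: float = 100.0
    colour: str = "blue"
    fragile: bool = False


@dataclass(frozen=True)
class GripperConfig:
    """Rule constants of the Prosthesis Gripper engine.

    Printed game rules: grip activation at a command of +/-25 with all
    other DoFs at or below 24, a ten-second activation timeout, a hard
    aperture cap of 1.7 object widths with sparks above 1.5, and 1000
    points per successful release. The remaining motion/scoring constants
    are engine choices, logged with each episode.
    """

    activation_threshold: float = 25.0
    coactivation_max: float = 24.0
    grip_timeout_s: float = 10.0
    aperture_cap_ratio: float = 1.7
    sparks_ratio: float = 1.5
    release_points: int = 1000

    tracking_dof: int = 1         # command slot steering the avatar
    track_gain: float = 40.0      # avatar speed at full command, units/s
    light_speed: float = 20.0     # units/s toward the screen edge
    screen_half_width: float = 100.0
    beam_distance: float = 15.0   # close enough: points awarded
    lose_distance: float = 40.0   # too far: points lost
    beam_points_per_s: float = 10.0
    loss_points_per_s: float = 5.0
    dwell_s: float = 1.0          # time under the stopped light to dispense

    open_rate: float = 1.0        # widths/s at full open command
    close_rate: float = 2.0       # widths/s at full pinch command
    fragile_close_speed: float = 1.0  # widths/s; faster closing breaks
    objects: tuple[GripperObject, ...] = (
        GripperObject(100.0, "blue", False),
        GripperObject(100.0, "red", False),
        GripperObject(100.0, "blue", True),
        GripperObject(100.0, "red", True),
    )


def grip_activation(cmd: Sequence[float], colour: str,
                    cfg: GripperConfig | None = None) -> bool:
    """The printed grip-activation rule.

    True iff the pinch-axis command reaches +/-25 with the sign matching the
    dispenser colour (blue -> fine pinch, positive; red -> lateral pinch,
    negative) while every other DoF stays within 0..+/-24.
    """
    cfg = cfg or GripperConfig()
    c = np.asarray(cmd, dtype=float)
    if c.shape != (4,):
        raise ValueError(f"expected a 4-DoF command vector, got {c.shape}")
    sign = 1.0 if colour == "blue" else -1.0
    if c[0] * sign < cfg.activation_threshold:
        return False
    return bool(np.all(np.abs(c[[1, 2, 3]]) <= cfg.coactivation_max))


def sparks_active(aperture: float, width: float,
                  cfg: GripperConfig | None = None) -> bool:
    """Sparks warn when the gripper is open beyond 1.5 object widths."""
    cfg = cfg or GripperConfig()
    return aperture > cfg.sparks_ratio * width


@dataclass(frozen=True)
class GripperState:
    """Full engine state; ``phase`` is one of tracking/dispense/grasp/release."""

    phase: str = "tracking"
    avatar_x: float = 0.0
    light_x: float = 0.0
    light_target: int = 1          # +1 right, -1 left
    light_moving: bool = True
    dwell_s: float = 0.0
    phase_t: float = 0.0
    object: GripperObject | None = None
    object_index: int = 0
    active_grip: str | None = None  # "fine" | "lateral"
    aperture: float = 0.0           # same length units as object width
    admitted: bool = False          # aperture has opened past the object
    force_close_pending: bool = False
    sparks: bool = False
    score: float = 0.0


def gripper_initial_state(cfg: GripperConfig | None = None) -> GripperState:
    return GripperState()


def _reset_to_tracking(state: GripperState, advance_object: bool) -> GripperState:
    return replace(
        state,
        phase="tracking",
        avatar_x=0.0,
        light_x=0.0,
        light_target=-state.light_target,
        light_moving=True,
        dwell_s=0.0,
        phase_t=0.0,
        object=None,
        object_index=state.object_index + (1 if advance_object else 0),
        active_grip=None,
        aperture=0.0,
        admitted=False,
        force_close_pending=False,
        sparks=False,
    )


def gripper_step(
    state: GripperState,
    cmd: Sequence[float],
    cfg: GripperConfig | None = None,
    dt: float = 0.05,
) -> tuple[GripperState, list[str]]:
    """Advance the Prosthesis Gripper by one tick on a 4-DoF command."""
    cfg = cfg or GripperConfig()
    c = np.asarray(cmd, dtype=float)
    if c.shape != (4,):
        raise ValueError(f"expected a 4-DoF command vector, got {c.shape}")
    events: list[str] = []

    if state.phase == "tracking":
        light_x, moving = state.light_x, state.light_moving
        if moving:
            light_x += cfg.light_speed * state.light_target * dt
            if abs(light_x) >= cfg.screen_half_width:
                light_x = cfg.screen_half_width * state.light_target
                moving = False
                events.append("light_stopped")
        avatar = float(np.clip(
            state.avatar_x + cfg.track_gain * (c[cfg.tracking_dof] / 100.0) * dt,
            -cfg.screen_half_width, cfg.screen_half_width,
        ))
        dist = abs(avatar - light_x)
        score = state.score
        if dist <= cfg.beam_distance:
            score += cfg.beam_points_per_s * dt
        elif dist > cfg.lose_distance:
            score -= cfg.loss_points_per_s * dt
        dwell = state.dwell_s
        if not moving and dist <= cfg.beam_distance:
            dwell += dt
            if dwell >= cfg.dwell_s:
                obj = cfg.objects[state.object_index % len(cfg.objects)]
                events.append(f"dispense:{obj.colour}")
                return (
                    replace(state, phase="dispense", light_x=light_x,
                            light_moving=False, avatar_x=avatar, dwell_s=0.0,
                            phase_t=0.0, object=obj, score=score),
                    events,
                )
        elif not moving:
            dwell = 0.0
        return (
            replace(state, avatar_x=avatar, light_x=light_x,
                    light_moving=moving, dwell_s=dwell, score=score),
            events,
        )

    if state.phase == "dispense":
        assert state.object is not None
        phase_t = state.phase_t + dt
        if grip_activation(c, state.object.colour, cfg):
            grip = "fine" if state.object.colour == "blue" else "lateral"
            events.append(f"grip_activated:{grip}")
            return (
                replace(state, phase="grasp", phase_t=0.0, active_grip=grip,
                        aperture=0.0, admitted=False, sparks=False),
                events,
            )
        if phase_t >= cfg.grip_timeout_s:
            events.append("grip_timeout")
            return _reset_to_tracking(replace(state, phase_t=phase_t), False), events
        return replace(state, phase_t=phase_t), events

    if state.phase == "grasp":
        assert state.object is not None and state.active_grip is not None
        obj = state.object
        w = obj.width
        if state.force_close_pending:
            events.append("forced_close")
            return (
                replace(state, aperture=0.0, admitted=False,
                        force_close_pending=False, sparks=False,
                        phase_t=state.phase_t + dt),
                events,
            )
        open_cmd = max(float(c[3]), 0.0)
        pinch = float(c[0])
        grip_sign = 1.0 if state.active_grip == "fine" else -1.0
        closing_drive = max(pinch * grip_sign, 0.0)
        delta = 0.0
        if open_cmd > 0.0:
            delta = cfg.open_rate * w * (open_cmd / 100.0) * dt
        elif closing_drive > 0.0:
            delta = -cfg.close_rate * w * (closing_drive / 100.0) * dt
        aperture = state.aperture + delta
        admitted = state.admitted
        pending = False
        if aperture >= cfg.aperture_cap_ratio * w:
            aperture = cfg.aperture_cap_ratio * w
            pending = True
            events.append("aperture_cap")
        aperture = max(aperture, 0.0)
        if aperture >= w:
            admitted = True
        if (
            delta < 0.0
            and admitted
            and obj.fragile
            and (-delta / dt) > cfg.fragile_close_speed * w
        ):
            events.append("object_broken")
            return _reset_to_tracking(state, True), events
        if delta < 0.0 and admitted and aperture <= w:
            events.append("grasped")
            return (
                replace(state, phase="release", aperture=w, admitted=True,
                        phase_t=0.0, sparks=False),
                events,
            )
        sparks = sparks_active(aperture, w, cfg)
        if sparks and not state.sparks:
            events.append("sparks")
        return (
            replace(state, aperture=aperture, admitted=admitted,
                    force_close_pending=pending, sparks=sparks,
                    phase_t=state.phase_t + dt),
            events,
        )

    if state.phase == "release":
        if float(c[3]) >= cfg.activation_threshold:
            events.append("released")
            new = _reset_to_tracking(state, True)
            return replace(new, score=new.score + cfg.release_points), events
        return replace(state, phase_t=state.phase_t + dt), events

    raise ValueError(f"unknown phase {state.phase!r}")


def episode_record(state, cfg, t: float, events: list[str]) -> dict:
    """One JSON-serializable line of an episode log (config included once
    at t=0 by the runners in :mod:`myogym.cli`)."""
    d = asdict(state)
    if isinstance(state, GripperState) and state.object is not None:
        d["object"] = asdict(state.object)
    return {"t": round(t, 6), "events": events, "state": d}
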