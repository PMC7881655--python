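"""MyoBox and Prosthesis Gripper engine rules."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from myogym.games import (
    Direction,
    GripperConfig,
    GripperObject,
    MyoBoxConfig,
    avatar_direction,
    grip_activation,
    gripper_initial_state,
    gripper_step,
    myobox_initial_state,
    myobox_step,
    sparks_active,
)


class TestAvatarDirection:
    def test_uniform_activation_cancels(self):
        assert avatar_direction([2.0] * 8) == (0.0, 0.0)

    def test_upper_triplet_drives_up(self):
        d = avatar_direction([0, 1, 1, 1, 0, 0, 0, 0])
        assert d.y == pytest.approx(1.0) and d.x == pytest.approx(0.0)

    def test_mixed_pattern(self):
        d = avatar_direction([1, 0, 0, 0, 0, 0, 0, 1])
        assert d.y == pytest.approx(-1 / 3)
        assert d.x == pytest.approx(2 / 3)

    def test_wrong_arity_rejected(self):
        with pytest.raises(ValueError, match="8"):
            avatar_direction([1.0] * 7)

    @settings(deadline=None, max_examples=60)
    @given(st.lists(st.floats(0, 10), min_size=8, max_size=8),
           st.floats(0, 5))
    def test_positive_homogeneity(self, rms, c):
        d1 = avatar_direction(rms)
        d2 = avatar_direction([c * r for r in rms])
        assert d2.x == pytest.approx(c * d1.x, abs=1e-9)
        assert d2.y == pytest.approx(c * d1.y, abs=1e-9)


class TestMyoBox:
    def test_zero_direction_leaves_ball_in_place(self):
        state = myobox_initial_state()
        new, events = myobox_step(state, Direction(0, 0))
        assert (new.x, new.y) == (state.x, state.y)
        assert events == []

    def test_leaving_platform_resets_ball(self):
        cfg = MyoBoxConfig()
        state = replace(myobox_initial_state(cfg), x=cfg.platform_width / 2)
        new, events = myobox_step(state, Direction(5, 0), cfg, dt=0.1)
        assert "fell_off_platform" in events
        assert (new.x, new.y) == cfg.ball_start
        assert new.falls == 1
        assert new.score == state.score  # score kept within the session

    def test_box_collection_scores(self):
        cfg = MyoBoxConfig()
        state = myobox_initial_state(cfg)
        bx, by = state.boxes[0]
        state = replace(state, x=bx, y=by - cfg.box_radius / 2)
        new, events = myobox_step(state, Direction(0, 0), cfg)
        assert "box_collected" in events
        assert new.score == state.score + cfg.points_per_box
        assert len(new.boxes) == len(state.boxes) - 1

    def test_level_up_narrows_platform_until_minimum(self):
        cfg = MyoBoxConfig()
        state = myobox_initial_state(cfg)
        widths = [state.platform_width]
        for _ in range(12):  # clear all boxes repeatedly
            state = replace(state, boxes=state.boxes[:1],
                            x=state.boxes[0][0], y=state.boxes[0][1])
            state, events = myobox_step(state, Direction(0, 0), cfg)
            assert any(e.startswith("level_up") for e in events)
            widths.append(state.platform_width)
        for a, b in zip(widths, widths[1:]):
            assert b < a or a == cfg.platform_min_width
        assert widths[-1] == cfg.platform_min_width

    def test_deterministic_trajectory(self):
        cfg = MyoBoxConfig()
        moves = [Direction(np.sin(i), np.cos(i)) for i in range(40)]
        finals = []
        for _ in range(2):
            state = myobox_initial_state(cfg)
            for d in moves:
                state, _ = myobox_step(state, d, cfg)
            finals.append(state)
        assert finals[0] == finals[1]


def _dispense_state(colour="blue", fragile=False, width=100.0):
    obj = GripperObject(width=width, colour=colour, fragile=fragile)
    return replace(gripper_initial_state(), phase="dispense", object=obj,
                   light_moving=False)


def _grasp_state(colour="blue", fragile=False, width=100.0, aperture=0.0):
    grip = "fine" if colour == "blue" else "lateral"
    return replace(_dispense_state(colour, fragile, width), phase="grasp",
                   active_grip=grip, aperture=aperture,
                   admitted=aperture >= width)


class TestGripActivation:
    def test_threshold_boundary(self):
        assert grip_activation([25, 0, 0, 0], "blue")
        assert not grip_activation([24, 0, 0, 0], "blue")
        assert grip_activation([-25, 0, 0, 0], "red")
        assert not grip_activation([25, 0, 0, 0], "red")  # wrong sign

    def test_coactivation_limit(self):
        assert grip_activation([40, 24, -24, 24], "blue")
        assert not grip_activation([40, 25, 0, 0], "blue")
        assert not grip_activation([40, 0, 0, -25], "blue")


class TestGripperPhases:
    def test_dispense_activation_enters_grasp(self):
        state, events = gripper_step(_dispense_state("blue"), [25, 0, 0, 0])
        assert state.phase == "grasp"
        assert state.active_grip == "fine"
        assert "grip_activated:fine" in events

    def test_dispense_subthreshold_does_nothing(self):
        state, events = gripper_step(_dispense_state("blue"), [24, 0, 0, 0])
        assert state.phase == "dispense" and events == []

    def test_dispense_timeout_returns_to_tracking(self):
        cfg = GripperConfig()
        state = _dispense_state("red")
        seen = []
        for _ in range(int(cfg.grip_timeout_s / 0.05) + 1):
            state, events = gripper_step(state, [0, 0, 0, 0], cfg)
            seen.extend(events)
            if state.phase != "dispense":
                break
        assert state.phase == "tracking"
        assert "grip_timeout" in seen

    def test_full_open_cap_sparks_and_forced_close(self):
        cfg = GripperConfig()
        state = _grasp_state("blue", width=100.0)
        apertures, all_events = [], []
        for _ in range(150):
            state, events = gripper_step(state, [0, 0, 0, 100], cfg)
            apertures.append(state.aperture)
            all_events.extend(events)
            if "forced_close" in events:
                break
        assert max(apertures) == pytest.approx(170.0)  # 1.7x width cap
        assert "sparks" in all_events
        assert "aperture_cap" in all_events
        assert "forced_close" in all_events
        assert state.aperture == 0.0
        # sparks exactly when aperture exceeded 1.5x the width
        sparked = [a for a in apertures if sparks_active(a, 100.0, cfg)]
        assert min(sparked) > 150.0

    def test_grasp_then_release_awards_1000_points(self):
        cfg = GripperConfig()
        state = _grasp_state("blue", width=100.0, aperture=120.0)
        # close gently with the matching (fine, +) grip
        for _ in range(100):
            state, events = gripper_step(state, [40, 0, 0, 0], cfg)
            if state.phase == "release":
                break
        assert state.phase == "release" and "grasped" in events
        assert state.aperture == 100.0
        score_before = state.score
        state, events = gripper_step(state, [0, 0, 0, 30], cfg)
        assert "released" in events
        assert state.score == score_before + cfg.release_points
        assert state.phase == "tracking"

    def test_wrong_grip_sign_does_not_close(self):
        state = _grasp_state("red", width=100.0, aperture=120.0)
        new, _ = gripper_step(state, [40, 0, 0, 0])  # fine on a red object
        assert new.aperture == state.aperture

    def test_fragile_object_breaks_on_forceful_close(self):
        cfg = GripperConfig()
        state = _grasp_state("blue", fragile=True, aperture=130.0)
        state, events = gripper_step(state, [100, 0, 0, 0], cfg)
        assert "object_broken" in events
        assert state.phase == "tracking"

    def test_fragile_object_survives_gentle_close(self):
        cfg = GripperConfig()
        state = _grasp_state("blue", fragile=True, aperture=130.0)
        for _ in range(100):
            state, events = gripper_step(state, [30, 0, 0, 0], cfg)
            if state.phase != "grasp":
                break
        assert state.phase == "release"

    def test_tracking_dwell_leads_to_dispense(self):
        cfg = GripperConfig()
        state = gripper_initial_state(cfg)
        events_seen = []
        for _ in range(400):  # light reaches the edge, then dwell 1 s
            cmd = [0, 100 * state.light_target, 0, 0]
            state, events = gripper_step(state, cmd, cfg)
            events_seen.extend(events)
            if state.phase == "dispense":
                break
        assert state.phase == "dispense"
        assert "light_stopped" in events_seen
        assert state.object is not None

    def test_tracking_awards_and_deducts_points(self):
        cfg = GripperConfig()
        near = replace(gripper_initial_state(cfg), avatar_x=0.0)
        state, _ = gripper_step(near, [0, 0, 0, 0], cfg, dt=0.05)
        assert state.score > 0  # in the beam near the centre light
        far = replace(gripper_initial_state(cfg), avatar_x=90.0)
        state, _ = gripper_step(far, [0, 0, 0, 0], cfg, dt=0.05)
        assert state.score < 0

    def test_trajectory_is_deterministic(self):
        cfg = GripperConfig()
        rng = np.random.default_rng(4)
        cmds = rng.uniform(-100, 100, size=(200, 4))
        finals = []
        for _ in range(2):
            state = gripper_initial_state(cfg)
            log = []
            for cmd in cmds:
                state, events = gripper_step(state, cmd, cfg)
                log.append((state, tuple(events)))
            finals.append(log)
        assert finals[0] == finals[1]

    @settings(deadline=None, max_examples=25)
    @given(st.lists(st.lists(st.floats(-100, 100), min_size=4, max_size=4),
                    min_size=1, max_size=60))
    def test_aperture_never_exceeds_cap(self, cmds):
        cfg = GripperConfig()
        state = _grasp_state("blue", width=100.0)
        for cmd in cmds:
            state, _ = gripper_step(state, cmd, cfg)
            if state.phase == "grasp":
                assert state.aperture <= cfg.aperture_cap_ratio * 100.0 + 1e-9
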