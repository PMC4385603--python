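import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from banmon.config import STANDARD_GRAVITY, PipelineConfig
from banmon.fusion import FusedSample
from banmon.quatmath import Quaternion, from_axis_angle
from banmon.state_evaluator import (
    HORIZONTAL,
    MOVING,
    STATIONARY,
    VERTICAL,
    InsufficientDataError,
    NodeStates,
    UserProfile,
    amvd,
    amvd_stream,
    detect_steps,
    dynamic_acceleration,
    gait_metrics,
    integrate_velocity,
    step_force,
    update_movement_state,
    update_orientation_state,
)

IDENT = Quaternion.identity()


def _fused(accel, q=IDENT, t=0.0):
    return FusedSample(t=t, q=q, accel=np.asarray(accel, dtype=float))


class TestDynamicAcceleration:
    def test_upright_at_rest_cancels_gravity(self):
        assert np.allclose(dynamic_acceleration(_fused([0, 0, 1])), 0.0, atol=1e-12)

    def test_flipped_node_cancels_gravity(self):
        # oracle: rotate (0,0,-1) by 180 deg about x -> (0,0,1), minus gravity
        q = from_axis_angle([1, 0, 0], math.pi)
        assert np.allclose(dynamic_acceleration(_fused([0, 0, -1], q=q)), 0.0, atol=1e-9)

    def test_excess_half_g(self):
        out = dynamic_acceleration(_fused([0, 0, 1.5]))
        assert out[2] == pytest.approx(4.906432664, abs=1e-9)


class TestVelocity:
    def test_zero_accel_zero_velocity(self):
        a = np.zeros((50, 3))
        v = integrate_velocity(a, [MOVING] * 50, dt=0.02)
        assert np.allclose(v, 0.0)

    def test_constant_accel_closed_form(self):
        n = 51  # 1 s at 50 Hz
        a = np.tile([1.0, 0.0, 0.0], (n, 1))
        v = integrate_velocity(a, [MOVING] * n, dt=0.02)
        assert v[-1, 0] == pytest.approx(1.0, abs=1e-9)

    def test_zupt_resets_on_stationary(self):
        n = 30
        a = np.tile([1.0, 0.0, 0.0], (n, 1))
        states = [MOVING] * 20 + [STATIONARY] + [MOVING] * 9
        v = integrate_velocity(a, states, dt=0.02)
        assert v[20, 0] == 0.0
        assert v[19, 0] > 0.0

    @given(st.integers(0, 2**31))
    @settings(max_examples=25, deadline=None)
    def test_zupt_conservation(self, seed):
        rng = np.random.default_rng(seed)
        n = 100
        a = rng.normal(0, 3, size=(n, 3))
        states = [MOVING if rng.random() < 0.6 else STATIONARY for _ in range(n)]
        v = integrate_velocity(a, states, dt=0.02)
        for i, s in enumerate(states):
            if s == STATIONARY:
                assert np.all(v[i] == 0.0)


class TestAMVD:
    def test_zero_variance_stationary(self):
        stat, moving = amvd([1.0] * 20, gamma=0.0013, N=20)
        assert stat == 0.0 and not moving

    def test_alternating_hand_computed(self):
        # 0.5/1.5 alternating: mean 1.0, each deviation 0.5 -> statistic 0.25
        window = [0.5, 1.5] * 10
        stat, moving = amvd(window, gamma=0.0013, N=20)
        assert stat == pytest.approx(0.25, abs=1e-12)
        assert moving

    def test_defaults_from_profile(self):
        prof = UserProfile()
        assert prof.amvd_gamma == 0.0013
        assert prof.amvd_window == 20

    def test_short_window_rejected(self):
        with pytest.raises(InsufficientDataError):
            amvd([1.0] * 10, gamma=0.0013, N=20)

    @given(st.integers(0, 2**31))
    @settings(max_examples=30, deadline=None)
    def test_stream_equals_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        mags = rng.normal(1.0, 0.1, size=60)
        stats, moving = amvd_stream(mags, gamma=0.0013, N=20)
        for i in range(19, 60):
            window = mags[i - 19 : i + 1]
            expected = float(np.mean((window - window.mean()) ** 2))
            assert stats[i] == pytest.approx(expected, abs=1e-12)
            assert moving[i] == (expected >= 0.0013)

    def test_stream_warmup_is_stationary(self):
        stats, moving = amvd_stream(np.linspace(0, 5, 19), gamma=0.0013, N=20)
        assert not moving.any()


class TestMovementState:
    def test_all_false(self):
        assert update_movement_state([False] * 5) == [STATIONARY] * 5

    def test_single_true(self):
        states = update_movement_state([False, True, False])
        assert states == [STATIONARY, MOVING, STATIONARY]

    def test_one_to_one_with_amvd(self, rng):
        flags = rng.random(50) < 0.5
        states = update_movement_state(flags)
        assert all((s == MOVING) == f for s, f in zip(states, flags))


class TestOrientationState:
    def test_vertical_small_tilt_stays(self, cfg):
        prof = UserProfile()
        assert update_orientation_state(5.0, VERTICAL, prof, "chest", cfg) == VERTICAL

    def test_vertical_enters_transition_interval(self, cfg):
        prof = UserProfile()
        assert update_orientation_state(80.0, VERTICAL, prof, "chest", cfg) == HORIZONTAL

    def test_hysteresis_holds_horizontal(self, cfg):
        # horizontal's interval is [0, 30]; 80 deg is outside -> no flip back
        prof = UserProfile()
        assert update_orientation_state(80.0, HORIZONTAL, prof, "chest", cfg) == HORIZONTAL

    def test_tilt_range_validated(self, cfg):
        with pytest.raises(ValueError):
            update_orientation_state(200.0, VERTICAL, UserProfile(), "chest", cfg)

    def test_single_ramp_single_transition(self, cfg):
        # synthetic tilt ramp crossed once -> at most one transition
        prof = UserProfile()
        tilts = np.concatenate([np.zeros(20), np.linspace(0, 90, 50), np.full(30, 90.0)])
        state = VERTICAL
        transitions = 0
        for tv in tilts:
            new = update_orientation_state(float(tv), state, prof, "leg", cfg)
            transitions += new != state
            state = new
        assert transitions == 1
        assert state == HORIZONTAL

    def test_profile_override(self, cfg):
        prof = UserProfile(transition_intervals={"leg": {VERTICAL: (20.0, 180.0)}})
        assert update_orientation_state(25.0, VERTICAL, prof, "leg", cfg) == HORIZONTAL


class TestSteps:
    def test_flat_stream_no_steps(self):
        t = np.arange(500) * 0.02
        assert detect_steps(t, np.zeros(500), 0.02) == []

    def test_below_threshold_no_steps(self):
        t = np.arange(500) * 0.02
        wave = 1.0 * np.sin(2 * math.pi * 1.8 * t)  # ~0.1 g p2p excursion
        assert detect_steps(t, wave, 0.02) == []

    def test_sinusoidal_gait_count(self):
        # 1.8 Hz for 10 s -> 18 +- 1 steps
        t = np.arange(500) * 0.02
        wave = 3.0 * np.sin(2 * math.pi * 1.8 * t)
        steps = detect_steps(t, wave, 0.02)
        assert 17 <= len(steps) <= 19

    def test_refractory_prevents_double_count(self):
        t = np.arange(500) * 0.02
        wave = 3.0 * np.sin(2 * math.pi * 1.8 * t) + 0.3 * np.sin(2 * math.pi * 11.0 * t)
        steps = detect_steps(t, wave, 0.02, refractory_s=0.4)
        assert len(steps) <= 19

    def test_moving_mask_gates_detection(self):
        t = np.arange(500) * 0.02
        wave = 3.0 * np.sin(2 * math.pi * 1.8 * t)
        steps = detect_steps(t, wave, 0.02, moving=np.zeros(500, dtype=bool))
        assert steps == []


class TestGaitMetrics:
    def test_no_steps(self):
        t = np.arange(100) * 0.02
        lengths, dist, cadence = gait_metrics([], np.ones(100), t, (0.0, 2.0), 0.02)
        assert lengths == [] and dist == 0.0 and cadence == 0.0

    def test_constant_speed_step_length(self):
        from banmon.state_evaluator import StepEvent

        t = np.arange(200) * 0.02
        v = np.ones(200)  # 1 m/s
        steps = [StepEvent(t_start=0.5, t_impact=1.0, peak_accel=3.0)]
        lengths, dist, _ = gait_metrics(steps, v, t, (0.0, 4.0 - 0.02), 0.02)
        assert lengths[0] == pytest.approx(0.5, abs=0.02)
        assert dist == pytest.approx(sum(lengths))

    def test_cadence_is_count_over_duration(self):
        from banmon.state_evaluator import StepEvent

        t = np.arange(500) * 0.02
        steps = [
            StepEvent(t_start=i * 0.5, t_impact=i * 0.5 + 0.25, peak_accel=1.0)
            for i in range(18)
        ]
        _, _, cadence = gait_metrics(steps, np.ones(500), t, (0.0, 10.0), 0.02)
        assert cadence == pytest.approx(1.8)

    def test_zero_duration_bout_rejected(self):
        with pytest.raises(ValueError):
            gait_metrics([], np.ones(10), np.arange(10) * 0.02, (1.0, 1.0), 0.02)

    @given(st.integers(0, 2**31))
    @settings(max_examples=20, deadline=None)
    def test_distance_equals_sum_of_lengths(self, seed):
        from banmon.state_evaluator import StepEvent

        rng = np.random.default_rng(seed)
        t = np.arange(400) * 0.02
        v = np.abs(rng.normal(1.0, 0.3, 400))
        impacts = np.sort(rng.uniform(0.5, 7.5, size=8))
        steps = [
            StepEvent(t_start=float(max(0.0, ti - 0.4)), t_impact=float(ti), peak_accel=1.0)
            for ti in impacts
        ]
        lengths, dist, _ = gait_metrics(steps, v, t, (0.0, 7.98), 0.02)
        assert dist == pytest.approx(sum(lengths), abs=1e-12)


class TestStepForce:
    def test_product(self):
        assert step_force(80.0, 12.0) == pytest.approx(960.0)

    def test_zero_peak(self):
        assert step_force(70.0, 0.0) == 0.0

    def test_invalid_weight(self):
        with pytest.raises(ValueError):
            step_force(0.0, 1.0)

    @given(st.floats(1.0, 200.0), st.floats(0.0, 100.0))
    def test_matches_product_oracle(self, w, a):
        assert step_force(w, a) == pytest.approx(w * a, rel=1e-12)


class TestNodeStates:
    def test_valid(self):
        NodeStates(movement=MOVING, orientation=VERTICAL)

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            NodeStates(movement="running", orientation=VERTICAL)


class TestProfile:
    def test_interval_validation(self):
        with pytest.raises(ValueError):
            UserProfile(normal_intervals={"hip": {"tilt": (10.0, 5.0)}})

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            UserProfile(weight_kg=-1.0)

    def test_json_round_trip(self, tmp_path, profile):
        path = tmp_path / "profile.json"
        profile.to_json(path)
        loaded = UserProfile.from_json(path)
        assert loaded.weight_kg == profile.weight_kg
        assert loaded.normal_intervals == profile.normal_intervals
        assert loaded.amvd_gamma == profile.amvd_gamma
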