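"""Trial/session engine: dynamics law, reset rules, landing, determinism."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from supergee.controller import IdealBangBangPolicy, NullPolicy, _IntervalPlan
from supergee.task import (
    ControllerContractError,
    EVENT_EARLY_EXIT,
    EVENT_GO_CUE,
    EVENT_LANDED,
    InvalidStateError,
    TaskConfig,
    TrialState,
    _integrate,
    run_session,
    run_session_arrays,
    run_trial,
    step_dynamics,
)

from _reference import RandomIntervalPolicy


class TestStepDynamics:
    def test_coasting_conserves_velocity_exactly(self, task_config):
        s = TrialState(time=2.0, position=0.1, velocity=0.5, phase="go")
        s2 = step_dynamics(s, 0.01, task_config)
        assert s2.velocity == 0.5
        assert s2.position == pytest.approx(0.1 + 0.005, abs=1e-15)

    def test_constant_thrust_reaches_a_times_t(self, task_config):
        s = TrialState(phase="go", key_right=True)
        for _ in range(100):
            s = step_dynamics(s, 0.01, task_config)
        assert abs(s.velocity - 2.0) < 1e-12

    def test_matches_closed_form_at_fine_step(self, task_config):
        # thrust for 0.5 s then coast to 1.0 s; closed form a*tau^2/2 + a*tau*(t-tau)
        dt = 1e-4
        s = TrialState(phase="go", key_right=True)
        for _ in range(int(0.5 / dt)):
            s = step_dynamics(s, dt, task_config)
        s = TrialState(time=s.time, position=s.position, velocity=s.velocity, phase="go")
        for _ in range(int(0.5 / dt)):
            s = step_dynamics(s, dt, task_config)
        expected = 2.0 * 0.5**2 / 2 + 2.0 * 0.5 * 0.5
        assert s.position == pytest.approx(expected, abs=1e-3)

    def test_non_finite_state_rejected(self, task_config):
        with pytest.raises(InvalidStateError):
            step_dynamics(TrialState(position=math.nan, phase="go"), 0.01, task_config)

    @settings(derandomize=True, deadline=None, max_examples=25)
    @given(data=st.data())
    def test_velocity_constant_wherever_net_force_zero(self, data, task_config):
        n = 80
        kL = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        kR = np.array(data.draw(st.lists(st.booleans(), min_size=n, max_size=n)))
        x, v = _integrate(kL[None, :], kR[None, :], task_config)
        dv = np.diff(v[0])
        coasting = (kL == kR)[:-1]  # both up or both down -> zero net force
        assert np.all(dv[coasting] == 0.0)


class TestTrial:
    def test_null_controller_never_moves_and_fails(self, task_config):
        log = run_trial(task_config, NullPolicy(), 0)
        assert not log.success
        assert np.all(log.positions == 0.0)
        assert not any(ev == EVENT_LANDED for _, ev in log.events)

    def test_ideal_bang_bang_lands_at_predicted_time(self, task_config):
        # closed form: thrust tau = sqrt(d/a); braking starts at x = d/2 with
        # v = a*tau; the target boundary (d - r) is entered during braking at
        # tau_b solving v*tau_b - a*tau_b^2/2 = d/2 - r, and the continuous
        # landing second runs from that entry
        a = task_config.force_accel
        d = task_config.planet_distance
        r = task_config.planet_radius
        tau = math.sqrt(d / a)
        v1 = a * tau
        tau_b = (v1 - math.sqrt(v1**2 - 2 * a * (d / 2 - r))) / a
        t_enter = task_config.hold_duration + tau + tau_b
        log = run_trial(task_config, IdealBangBangPolicy(task_config), 0)
        assert log.success
        landed = next(t for t, ev in log.events if ev == EVENT_LANDED)
        assert landed == pytest.approx(t_enter + task_config.landing_duration, abs=0.05)
        # and the cursor is at rest at the target center shortly after 2*tau
        i_stop = int(round((task_config.hold_duration + 2 * tau) * task_config.sample_rate))
        assert log.velocities[i_stop] == pytest.approx(0.0, abs=0.05)
        assert log.positions[i_stop] == pytest.approx(d, abs=task_config.planet_radius)
        # no samples beyond the landed event
        assert log.times[-1] == pytest.approx(landed, abs=1e-9)

    def test_single_early_exit_resets_then_trial_completes(self, task_config):
        class EarlyOnce:
            def __init__(self):
                self.calls = 0
                self.good = IdealBangBangPolicy(task_config)

            def plan_trial(self, i, rng):
                self.calls += 1
                if self.calls == 1:
                    return _IntervalPlan(t_go=1.0, tau_r=0.5, t_rev=2.2, tau_l=0.4)
                return self.good.plan_trial(i, rng)

        log = run_trial(task_config, EarlyOnce(), 0)
        resets = [t for t, ev in log.events if ev == EVENT_EARLY_EXIT]
        assert len(resets) == 1
        assert log.success  # trial continued after the reset and finished

    def test_reset_soundness_post_reset_timeline_clean(self, task_config):
        sa = run_session_arrays(task_config, RandomIntervalPolicy(), 7)
        # final-attempt arrays are the post-reset timeline
        pre_go = np.abs(sa.x[:, : task_config.i_hold]) > task_config.planet_radius
        assert not pre_go.any()

    def test_controller_contract_enforced(self, task_config):
        class BadPolicy:
            def plan_trial(self, i, rng):
                class P:
                    def keys(self, t):
                        return np.zeros(t.shape, dtype=int), np.zeros(t.shape, dtype=int)

                return P()

        with pytest.raises(ControllerContractError):
            run_trial(task_config, BadPolicy(), 0)


class TestSession:
    def test_session_has_configured_trial_count(self, task_config):
        session = run_session(task_config, NullPolicy(), 0)
        assert len(session.trial_logs) == task_config.n_trials

    def test_bang_bang_feasibility_all_75_trials(self, task_config):
        sa = run_session_arrays(task_config, IdealBangBangPolicy(task_config), 0)
        assert int(sa.success.sum()) == task_config.n_trials

    def test_all_success_planet_chain_distinct_and_linked(self, task_config):
        session = run_session(task_config, IdealBangBangPolicy(task_config), 0)
        seq = session.planet_sequence
        assert len(set(seq)) == task_config.n_trials
        for k in range(1, len(seq)):
            assert seq[k][0] == seq[k - 1][1]

    def test_failure_repeats_planet_pair(self, task_config):
        session = run_session(task_config, NullPolicy(), 0)
        assert set(session.planet_sequence) == {(0, 1)}

    def test_determinism_same_seed_identical_logs(self, task_config):
        a = run_session(task_config, RandomIntervalPolicy(), 42, timestamp="t")
        b = run_session(task_config, RandomIntervalPolicy(), 42, timestamp="t")
        for la, lb in zip(a.trial_logs, b.trial_logs):
            np.testing.assert_array_equal(la.times, lb.times)
            np.testing.assert_array_equal(la.positions, lb.positions)
            np.testing.assert_array_equal(la.key_left, lb.key_left)
            assert la.events == lb.events
            assert la.success == lb.success

    def test_sample_spacing_uniform(self, task_config):
        session = run_session(task_config, RandomIntervalPolicy(), 3)
        for log in session.trial_logs:
            gaps = np.diff(log.times)
            assert np.all(np.abs(gaps - task_config.dt) < 1e-9)

    def test_go_cue_recorded_at_hold_end(self, task_config):
        log = run_trial(task_config, NullPolicy(), 0)
        go = [t for t, ev in log.events if ev == EVENT_GO_CUE]
        assert go == [pytest.approx(task_config.hold_duration)]


class TestTaskConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"trial_duration": 5.0},
            {"landing_duration": 3.5},
            {"planet_radius": 0.6},
            {"sample_rate": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TaskConfig(**kwargs)
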