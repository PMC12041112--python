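"""Agent learning rule, movement policy, trial/session/cohort simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cogavoid.sim_engine import (
    EYE_HEIGHT,
    AgentParams,
    AgentState,
    TrialContext,
    agent_policy_step,
    null_agent_params,
    run_cohort,
    run_session,
    run_trial,
    update_association,
)
from cogavoid.task_model import (
    CS_MINUS,
    CS_PLUS,
    ExperimentSpec,
    default_phase,
    build_experiment,
    load_template,
)
from cogavoid.stats import aggregate_by_condition, cohort_trial_table, paired_effect_size
from cogavoid.kinematics import summarize_session


class TestUpdateAssociation:
    def test_direct_substitution(self):
        assert update_association(0.0, 1, 0.5) == 0.5

    def test_zero_learning_rate(self):
        assert update_association(0.4, 1, 0.0) == 0.4

    def test_fixed_point_equals_reinforcement_rate(self):
        # under Bernoulli(0.75) outcomes the stationary mean of V is 0.75
        rng = np.random.default_rng(42)
        v, trace = 0.0, []
        for _ in range(20_000):
            v = update_association(v, int(rng.uniform() < 0.75), 0.2)
            trace.append(v)
        assert np.mean(trace[1000:]) == pytest.approx(0.75, abs=0.03)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            update_association(0.5, 1, 1.5)

    @given(st.lists(st.sampled_from([0, 1]), min_size=1, max_size=200),
           st.floats(0, 1))
    @settings(derandomize=True, max_examples=50)
    def test_association_stays_in_unit_interval(self, outcomes, alpha):
        v = 0.0
        for o in outcomes:
            v = update_association(v, o, alpha)
            assert 0.0 <= v <= 1.0


def _ctx(**kw) -> TrialContext:
    defaults = dict(
        condition=CS_PLUS, cs_position=(0.0, 1.0, 0.0), movement_allowed=True,
        instructed_approach=False, compliant=False, tracker_rate=90.0,
        room_half_width=4.0, room_half_depth=4.0,
    )
    defaults.update(kw)
    return TrialContext(**defaults)


class TestPolicyStep:
    def test_no_drive_is_noise_only(self):
        params = AgentParams(position_noise_sd=0.02)
        state = AgentState(position=np.array([0.0, EYE_HEIGHT, -2.0]))
        rng = np.random.default_rng(0)
        ctx = _ctx()
        for _ in range(90):  # 1 s
            state = agent_policy_step(state, params, ctx, 1 / 90, rng)
        disp = math.hypot(state.position[0] - 0.0, state.position[2] + 2.0)
        assert disp <= 3 * params.position_noise_sd

    def test_avoidance_drive_reaches_safe_distance(self):
        # V=1 > theta, start 1 m away, walk 1 m/s, safe distance 4 m
        params = AgentParams(position_noise_sd=0.0, heading_noise_sd=0.0)
        state = AgentState(position=np.array([0.0, EYE_HEIGHT, -1.0]),
                           associations={CS_PLUS: 1.0, CS_MINUS: 0.0})
        rng = np.random.default_rng(0)
        ctx = _ctx(room_half_width=6.0, room_half_depth=6.0)  # walls out of play
        for _ in range(270):  # 3 s at 90 Hz
            state = agent_policy_step(state, params, ctx, 1 / 90, rng)
        dist = math.hypot(state.position[0], state.position[2])
        assert dist == pytest.approx(4.0, abs=1e-6)

    def test_movement_disallowed_noise_only(self):
        params = AgentParams(position_noise_sd=0.01)
        state = AgentState(position=np.array([0.0, EYE_HEIGHT, -2.0]),
                           associations={CS_PLUS: 1.0, CS_MINUS: 0.0})
        rng = np.random.default_rng(1)
        ctx = _ctx(movement_allowed=False)
        for _ in range(90):
            state = agent_policy_step(state, params, ctx, 1 / 90, rng)
        disp = math.hypot(state.position[0], state.position[2] + 2.0)
        assert disp <= 3 * params.position_noise_sd

    def test_instructed_approach_overrides_avoidance(self):
        params = AgentParams(position_noise_sd=0.0, heading_noise_sd=0.0)
        state = AgentState(position=np.array([0.0, EYE_HEIGHT, -4.0]),
                           associations={CS_PLUS: 1.0, CS_MINUS: 0.0})
        rng = np.random.default_rng(0)
        ctx = _ctx(instructed_approach=True, compliant=True)
        for _ in range(int(4.0 * 90)):
            state = agent_policy_step(state, params, ctx, 1 / 90, rng)
        dist = math.hypot(state.position[0], state.position[2])
        assert dist == pytest.approx(params.stand_close_distance, abs=1e-6)

    def test_position_stays_in_room(self):
        params = AgentParams(position_noise_sd=1.0)  # violent drift
        state = AgentState(position=np.array([3.5, EYE_HEIGHT, 3.5]))
        rng = np.random.default_rng(2)
        ctx = _ctx()
        for _ in range(200):
            state = agent_policy_step(state, params, ctx, 1 / 90, rng)
            assert abs(state.position[0]) <= 4.0 and abs(state.position[2]) <= 4.0


def _make_trial(reinforced=True, condition=CS_PLUS, cs_duration=9.0,
                start=(0.0, 0.0, -2.0)):
    from cogavoid.task_model import TrialSpec

    return TrialSpec(
        trial_number=1, condition=condition, reinforced=reinforced,
        iti=10.0, cs_duration=cs_duration,
        scheduled_us_onset=8.0 if reinforced else None,
        phase_kind="avoidance_learning", start_position=start,
    )


class TestRunTrial:
    def _run(self, trial, state=None, params=None, us_visual_cue=True, seed=0):
        from cogavoid.task_model import USFieldSpec

        params = params or null_agent_params()
        state = state or AgentState(
            position=np.array([trial.start_position[0], EYE_HEIGHT,
                               trial.start_position[2]])
        )
        ctx = _ctx(condition=trial.condition)
        return run_trial(trial, ctx, state, params, np.random.default_rng(seed),
                         us_field=USFieldSpec(), us_visual_cue=us_visual_cue)

    def test_us_marker_at_8s_after_cs_onset(self):
        trace, events, _ = self._run(_make_trial())
        cs_on = next(e for e in events if e["event"] == "cs_on")
        us_on = next(e for e in events if e["event"] == "us_on")
        assert us_on["time_s"] - cs_on["time_s"] == pytest.approx(8.0)

    def test_trace_sample_count(self):
        trace, _, _ = self._run(_make_trial())
        assert abs(len(trace) - 810) <= 1  # 9 s at 90 Hz

    def test_us_not_perceived_beyond_audible_radius(self):
        # stationary agent 5 m out: delivered US is inaudible, outcome 0
        trial = _make_trial(start=(0.0, 0.0, -5.0))
        params = AgentParams(learning_rate=0.5, position_noise_sd=0.001)
        state = AgentState(position=np.array([0.0, EYE_HEIGHT, -5.0]))
        ctx = _ctx(room_half_width=6.0, room_half_depth=6.0)
        from cogavoid.task_model import USFieldSpec

        _, _, out = run_trial(trial, ctx, state, params, np.random.default_rng(0),
                              us_field=USFieldSpec(), us_visual_cue=False)
        assert out.associations[CS_PLUS] == 0.0

    def test_us_perceived_within_audible_radius(self):
        trial = _make_trial(start=(0.0, 0.0, -2.0))
        params = AgentParams(learning_rate=0.5, position_noise_sd=0.001)
        state = AgentState(position=np.array([0.0, EYE_HEIGHT, -2.0]))
        ctx = _ctx()
        from cogavoid.task_model import USFieldSpec

        _, _, out = run_trial(trial, ctx, state, params, np.random.default_rng(0),
                              us_field=USFieldSpec(), us_visual_cue=False)
        assert out.associations[CS_PLUS] == 0.5

    def test_visual_cue_makes_us_distance_independent(self):
        trial = _make_trial(start=(0.0, 0.0, -5.0))
        params = AgentParams(learning_rate=0.5, position_noise_sd=0.001)
        state = AgentState(position=np.array([0.0, EYE_HEIGHT, -5.0]))
        _, _, out = run_trial(trial, _ctx(), state, params,
                              np.random.default_rng(0), us_visual_cue=True)
        assert out.associations[CS_PLUS] == 0.5

    def test_inline_stepper_matches_policy_iteration_when_deterministic(self):
        # with zero noise the fast inlined trial loop must equal iterating
        # agent_policy_step exactly
        params = AgentParams(position_noise_sd=0.0, heading_noise_sd=0.0)
        trial = _make_trial(reinforced=False, start=(0.0, 0.0, -1.0))
        state = AgentState(position=np.array([0.0, EYE_HEIGHT, -1.0]),
                           associations={CS_PLUS: 1.0, CS_MINUS: 0.0})
        ctx = _ctx()
        trace, _, _ = run_trial(trial, ctx, state, params,
                                np.random.default_rng(0))
        ref = AgentState(position=np.array([0.0, EYE_HEIGHT, -1.0]),
                         associations={CS_PLUS: 1.0, CS_MINUS: 0.0})
        for k in range(len(trace)):
            ref = agent_policy_step(ref, params, ctx, 1 / 90, np.random.default_rng(0))
            np.testing.assert_allclose(trace.positions[k], ref.position, atol=1e-12)


class TestRunSessionAndCohort:
    def test_exp2_session_has_56_trials(self):
        spec = load_template("exp2")
        rng = np.random.default_rng(7)
        schedule = build_experiment(spec, 1, rng)
        session = run_session(schedule, null_agent_params(), rng, spec)
        assert len(session.trials) == 56  # 16+16+4+16+4

    def test_itis_within_phase_range(self):
        spec = load_template("exp3")
        rng = np.random.default_rng(8)
        schedule = build_experiment(spec, 1, rng)
        session = run_session(schedule, null_agent_params(), rng, spec)
        for t in session.trials:
            assert 9.0 <= t.iti <= 15.0

    def test_coin_events_only_during_transfer(self):
        spec = load_template("exp3")
        rng = np.random.default_rng(9)
        schedule = build_experiment(spec, 1, rng)
        session = run_session(schedule, AgentParams(), rng, spec)
        ev = session.events
        coins = ev[ev["event"].isin(["coin_spawn", "coin_collect"])]
        assert len(coins[coins["event"] == "coin_spawn"]) > 0
        # every coin event falls inside a transfer trial's CS period
        transfer = [t for t in session.trials if t.phase == "transfer"]
        windows = [(t.cs_on_time, t.cs_on_time + 21.0) for t in transfer]
        for ts in coins["time_s"]:
            assert any(lo <= ts <= hi for lo, hi in windows)

    def test_same_seed_reproduces_trial_tables(self, avoidance_only_spec):
        a = run_cohort(avoidance_only_spec, null_agent_params(), 3, seed=5)
        b = run_cohort(avoidance_only_spec, null_agent_params(), 3, seed=5)
        for sa, sb in zip(a, b):
            assert sa.trial_table().equals(sb.trial_table())
            for ta, tb in zip(sa.trials, sb.trials):
                np.testing.assert_array_equal(
                    ta.traces["head"].positions, tb.traces["head"].positions
                )

    def test_cohort_resizing_keeps_existing_participants(self, avoidance_only_spec):
        small = run_cohort(avoidance_only_spec, null_agent_params(), 2, seed=5)
        large = run_cohort(avoidance_only_spec, null_agent_params(), 4, seed=5)
        for s, l in zip(small, large):
            assert s.trial_table().equals(l.trial_table())

    def test_avoider_cohort_separates_conditions(self, avoidance_only_spec):
        sessions = run_cohort(avoidance_only_spec, AgentParams(), 8, seed=21)
        for s in sessions:
            summarize_session(s)
        table = cohort_trial_table(sessions)
        pairs = aggregate_by_condition(table, "mean_dist_m", "avoidance_learning")
        assert pairs["cs_plus"].mean() > pairs["cs_minus"].mean() + 0.5

    def test_null_cohort_shows_no_separation(self, avoidance_only_spec):
        sessions = run_cohort(avoidance_only_spec, null_agent_params(), 8, seed=22)
        for s in sessions:
            summarize_session(s)
        table = cohort_trial_table(sessions)
        pairs = aggregate_by_condition(table, "mean_dist_m", "avoidance_learning")
        es = paired_effect_size(pairs["cs_plus"], pairs["cs_minus"])
        assert abs(es.hedges_g) < 1.0

    def test_speed_never_exceeds_walk_speed_plus_noise(self):
        spec = ExperimentSpec(name="x", phases=[default_phase("avoidance_learning")])
        sessions = run_cohort(spec, AgentParams(), 2, seed=13)
        dt = 1.0 / spec.tracker_rate
        # 5-sigma bound on the per-step noise increment, both axes
        allowance = 5 * AgentParams().position_noise_sd * math.sqrt(dt) * math.sqrt(2)
        for s in sessions:
            for t in s.trials:
                tr = t.traces["head"]
                step = np.diff(tr.positions, axis=0)
                seg = np.hypot(step[:, 0], step[:, 2])
                assert seg.max() <= AgentParams().walk_speed * dt + allowance

    def test_agent_positions_within_room(self):
        spec = load_template("exp5")
        sessions = run_cohort(spec, AgentParams(), 2, seed=14)
        for s in sessions:
            for t in s.trials:
                tr = t.traces["head"]
                assert np.all(np.abs(tr.positions[:, 0]) <= 4.0)
                assert np.all(np.abs(tr.positions[:, 2]) <= 4.0)

    def test_event_timestamps_non_decreasing(self):
        spec = load_template("exp4")
        sessions = run_cohort(spec, AgentParams(), 1, seed=15)
        ts = sessions[0].events["time_s"].to_numpy()
        assert np.all(np.diff(ts) >= 0)

    def test_reinstatement_us_logged_with_condition_none(self):
        spec = load_template("exp4")
        sessions = run_cohort(spec, AgentParams(), 1, seed=16)
        ev = sessions[0].events
        none_us = ev[(ev["event"] == "us_on") & ev["payload_json"].str.contains('"none"')]
        assert len(none_us) == 1
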