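"""Trial generation constraints and the session state machine."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sdrst import (
    EngineError,
    FeedbackKind,
    GridSpec,
    InvalidResponseError,
    PerfectAgent,
    RandomAgent,
    ResponseEvent,
    SessionLog,
    SessionPhase,
    StateError,
    StimulusCategory,
    StimulusSpec,
    TaskConfig,
    Valence,
    advance_trial,
    apply_response,
    current_display,
    generate_trial_plan,
    preset,
    run_with_agent,
    start_session,
)

from conftest import geometric_stimuli


def respond(state, location, ts=None):
    ts = state.last_event_ts + 100 if ts is None else ts
    return apply_response(state, ResponseEvent(chosen_location=location, timestamp_ms=ts))


class TestTrialPlan:
    def test_locations_distinct_and_on_grid(self, minimal_config):
        plan = generate_trial_plan(minimal_config, 0, Valence.none)
        locs = [loc for _, loc in plan.items]
        assert len(plan.items) == minimal_config.max_items
        assert len(set(locs)) == len(locs)
        assert all(0 <= l < 16 for l in locs)

    def test_unique_condition_repeats_one_stimulus(self, minimal_config):
        plan = generate_trial_plan(minimal_config, 3, Valence.none)
        assert len({sid for sid, _ in plan.items}) == 1

    def test_varied_condition_all_distinct(self, varied_config):
        plan = generate_trial_plan(varied_config, 0, Valence.none)
        ids = [sid for sid, _ in plan.items]
        assert len(set(ids)) == len(ids) == varied_config.max_items

    def test_deterministic_in_config_and_index(self, minimal_config):
        a = generate_trial_plan(minimal_config, 5, Valence.none)
        b = generate_trial_plan(minimal_config, 5, Valence.none)
        assert a == b

    def test_plan_independent_of_other_trials(self, minimal_config):
        # trial i's plan depends only on (seed, i), not on n_trials
        bigger = minimal_config.with_updates(**{"n_trials": 30})
        assert (generate_trial_plan(minimal_config, 2, Valence.none)
                == generate_trial_plan(bigger, 2, Valence.none))

    def test_missing_valence_errors(self, minimal_config):
        with pytest.raises(EngineError, match="negative"):
            generate_trial_plan(minimal_config, 0, Valence.negative)

    def test_defined_choice_uses_listed_order(self, varied_config):
        cfg = varied_config.with_updates(**{"stimulus_choice": "defined"})
        plan = generate_trial_plan(cfg, 0, Valence.none)
        assert [sid for sid, _ in plan.items] == [s.stimulus_id for s in cfg.stimulus_set[:8]]

    @given(seed=st.integers(0, 2**31 - 1), trial=st.integers(0, 200),
           rows=st.integers(2, 5), cols=st.integers(2, 5))
    def test_distinctness_property(self, seed, trial, rows, cols):
        n_loc = rows * cols
        cfg = TaskConfig(
            stimulus_set=geometric_stimuli(min(n_loc, 8)),
            condition="varied",
            n_trials=1,
            max_items=min(n_loc, 8),
            grid=GridSpec(n_rows=rows, n_cols=cols),
            rng_seed=seed,
        )
        plan = generate_trial_plan(cfg, trial, Valence.none)
        locs = [loc for _, loc in plan.items]
        ids = [sid for sid, _ in plan.items]
        assert len(set(locs)) == len(locs)
        assert len(set(ids)) == len(ids)


class TestStateMachine:
    def test_session_plans_all_trials(self):
        assert len(start_session(preset("study_b")).plan) == 40

    def test_study_a_single_valence_slice(self):
        # restricting study a to one emotional valence leaves its 16 trials
        a = preset("study_a")
        cfg = a.with_updates(**{
            "n_trials": 16,
            "trials_per_valence": {Valence.negative: 16},
        })
        state = start_session(cfg)
        assert len(state.plan) == 16
        assert all(p.valence is Valence.negative for p in state.plan)

    def test_start_session_deterministic(self, minimal_config):
        assert start_session(minimal_config).plan == start_session(minimal_config).plan

    def test_first_display_forced_choice(self, minimal_config):
        state = start_session(minimal_config)
        disp = current_display(state)
        assert disp.step == 1 and len(disp.visible) == 1
        assert disp.target_location == disp.visible[0][1]
        _, _, correct = respond(state, disp.target_location)
        assert correct

    def test_display_stable_across_calls(self, minimal_config):
        state = start_session(minimal_config)
        assert current_display(state) == current_display(state)

    def test_persistence_of_visible_items(self, minimal_config):
        state = start_session(minimal_config)
        prev = None
        for _ in range(minimal_config.max_items):
            disp = current_display(state)
            if prev is not None:
                assert disp.visible[: len(prev)] == prev
            prev = disp.visible
            respond(state, disp.target_location)
        assert state.phase is SessionPhase.trial_ended

    def test_wrong_touch_ends_trial(self, minimal_config):
        state = start_session(minimal_config)
        respond(state, current_display(state).target_location)
        disp = current_display(state)
        old_location = disp.visible[0][1]
        _, _, correct = respond(state, old_location)
        assert not correct
        assert state.phase is SessionPhase.trial_ended
        assert state.log.events[-1]["span"] == 1

    def test_ceiling_records_full_span(self, minimal_config):
        state = start_session(minimal_config)
        for _ in range(minimal_config.max_items):
            respond(state, current_display(state).target_location)
        end = state.log.events[-1]
        assert end["type"] == "trial_end"
        assert end["span"] == minimal_config.max_items
        assert end["ended_by"] == "ceiling"

    def test_invalid_touch_logged_and_state_unchanged(self, minimal_config):
        state = start_session(minimal_config)
        disp = current_display(state)
        bad = next(l for l in range(16) if l != disp.target_location)
        with pytest.raises(InvalidResponseError):
            respond(state, bad)
        assert state.phase is SessionPhase.awaiting_response
        assert state.current_step == 1
        assert state.log.events[-1]["type"] == "invalid_touch"

    def test_phase_guards(self, minimal_config):
        state = start_session(minimal_config)
        with pytest.raises(StateError):
            advance_trial(state)  # still awaiting a response
        respond(state, current_display(state).target_location)
        disp = current_display(state)
        respond(state, disp.visible[0][1])  # mistake
        with pytest.raises(StateError):
            current_display(state)  # trial ended, nothing on screen
        advance_trial(state)
        assert state.current_trial == 1 and state.current_step == 1

    def test_session_ends_after_last_trial(self, minimal_config):
        state = start_session(minimal_config)
        while state.phase is not SessionPhase.session_ended:
            disp = current_display(state)
            respond(state, disp.target_location)
            if state.phase is SessionPhase.trial_ended:
                advance_trial(state)
        assert state.log.events[-1]["type"] == "session_end"
        with pytest.raises(StateError):
            advance_trial(state)

    def test_timestamps_monotone(self, study_b_random_log):
        ts = [e["timestamp_ms"] for e in study_b_random_log.events]
        assert all(a <= b for a, b in zip(ts, ts[1:]))

    def test_non_monotone_response_rejected(self, minimal_config):
        state = start_session(minimal_config)
        respond(state, current_display(state).target_location, ts=500)
        with pytest.raises(StateError, match="timestamp"):
            respond(state, current_display(state).target_location, ts=100)


class TestFeedback:
    def feedback_for(self, mode, correct, minimal_config):
        cfg = minimal_config.with_updates(**{"feedback_mode": mode})
        state = start_session(cfg)
        respond(state, current_display(state).target_location)
        if correct:
            return state.log.events  # inspect log for the correct touch
        disp = current_display(state)
        _, fb, _ = respond(state, disp.visible[0][1])
        return fb

    def test_auditory_tones(self, minimal_config):
        fb = self.feedback_for("auditory", correct=False, minimal_config=minimal_config)
        assert fb.kind is FeedbackKind.wrong_tone
        events = self.feedback_for("auditory", correct=True, minimal_config=minimal_config)
        assert any(e["type"] == "feedback" and e["kind"] == "correct_tone" for e in events)

    def test_reward_mode(self, minimal_config):
        events = self.feedback_for("auditory_plus_reward", correct=True,
                                   minimal_config=minimal_config)
        assert any(e["type"] == "feedback" and e["kind"] == "reward" for e in events)

    def test_no_feedback_events_when_disabled(self, study_b_random_log, minimal_config):
        cfg = minimal_config  # feedback_mode = none
        state = start_session(cfg)
        respond(state, current_display(state).target_location)
        assert not any(e["type"] == "feedback" for e in state.log.events)


class TestAgentHarness:
    def test_perfect_agent_hits_ceiling_everywhere(self):
        log = run_with_agent(preset("study_b"), PerfectAgent(), agent_seed=0)
        ends = [e for e in log.events if e["type"] == "trial_end"]
        assert len(ends) == 40
        assert all(e["span"] == 8 for e in ends)

    def test_replay_determinism(self):
        a = run_with_agent(preset("study_b"), RandomAgent(), agent_seed=3)
        b = run_with_agent(preset("study_b"), RandomAgent(), agent_seed=3)
        assert a.to_jsonl() == b.to_jsonl()

    def test_different_agent_seed_differs(self):
        a = run_with_agent(preset("study_b"), RandomAgent(), agent_seed=3)
        b = run_with_agent(preset("study_b"), RandomAgent(), agent_seed=4)
        assert a.to_jsonl() != b.to_jsonl()

    def test_log_jsonl_round_trip(self, study_b_random_log):
        text = study_b_random_log.to_jsonl()
        back = SessionLog.from_jsonl(text)
        assert back.events == study_b_random_log.events
        assert back.header == study_b_random_log.header

    def test_header_carries_agent_provenance(self, study_b_random_log):
        assert study_b_random_log.header["agent"]["name"] == "random"
        assert study_b_random_log.header["agent_seed"] == 42

    def test_metadata_recorded(self, minimal_config):
        log = run_with_agent(minimal_config, PerfectAgent(), agent_seed=0,
                             metadata={"participant": "sim-01", "age": 30})
        assert log.header["metadata"]["participant"] == "sim-01"
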