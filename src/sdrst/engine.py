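"""Trial generation and the event-driven SDRST session state machine.

A session is a fixed sequence of trials, each pre-drawn from the config seed.
Within a trial the display grows one stimulus at a time: at step ``k`` the
first ``k`` planned items are visible, the first ``k - 1`` at the locations
where they first appeared, and the participant must touch the newest (novel-
location) item.  A correct touch advances to step ``k + 1``; a wrong touch
ends the trial immediately; reaching ``max_items`` correct touches ends the
trial at ceiling.  Step 1 shows a single stimulus, so the first touch of a
trial cannot be wrong.

Randomness is splittable: trial ``i``'s plan is drawn from a generator seeded
by ``(rng_seed, i)``, so it does not depend on how many trials precede it.
Every event is appended to a :class:`SessionLog` with monotone millisecond
timestamps and can be serialised to JSON Lines for replay and scoring.
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from typing import Any, Iterable, Optional, Protocol

import numpy as np

from .config import (
    Condition,
    FeedbackMode,
    StimulusChoice,
    TaskConfig,
    Valence,
)

# Spawn key for the valence-order shuffle; larger than any trial index so the
# order stream never collides with a per-trial stream.
_ORDER_STREAM = 2**32


class EngineError(ValueError):
    """Raised when trial generation is impossible for the given config."""


class StateError(RuntimeError):
    """Raised when an operation is applied in the wrong session phase."""


class InvalidResponseError(ValueError):
    """Raised when a touch lands on a location with no visible stimulus."""


class SessionPhase(str, enum.Enum):
    awaiting_response = "awaiting_response"
    trial_ended = "trial_ended"
    session_ended = "session_ended"


class FeedbackKind(str, enum.Enum):
    correct_tone = "correct_tone"
    wrong_tone = "wrong_tone"
    reward = "reward"
    none = "none"


@dataclass(frozen=True)
class FeedbackEvent:
    kind: FeedbackKind


@dataclass(frozen=True)
class TrialPlan:
    """Pre-drawn (stimulus, location) sequence for one trial.

    Locations are pairwise distinct (each new stimulus appears in a location
    not yet occupied); stimulus identity follows the condition: all equal in
    ``unique``, pairwise distinct in ``varied``.
    """

    trial_index: int
    items: tuple[tuple[str, int], ...]
    condition: Condition
    valence: Valence
    category: str  # category of the trial's stimuli, or "mixed"


@dataclass(frozen=True)
class DisplaySpec:
    """What is on screen at step ``k``: the first ``k`` planned items, the
    newest of which occupies ``target_location``."""

    step: int
    visible: tuple[tuple[str, int], ...]
    target_location: int

    @property
    def visible_locations(self) -> tuple[int, ...]:
        return tuple(loc for _, loc in self.visible)


@dataclass(frozen=True)
class ResponseEvent:
    chosen_location: int
    timestamp_ms: int


@dataclass
class SessionLog:
    """Header (config echo, agent provenance, free-form session metadata such
    as participant demographics) plus the ordered event stream."""

    header: dict[str, Any]
    events: list[dict[str, Any]] = field(default_factory=list)

    def append(self, event: dict[str, Any]) -> None:
        self.events.append(event)

    def to_jsonl(self) -> str:
        lines = [json.dumps({"type": "header", **self.header},
                            sort_keys=True, separators=(",", ":"))]
        lines.extend(
            json.dumps(e, sort_keys=True, separators=(",", ":")) for e in self.events
        )
        return "\n".join(lines) + "\n"

    @classmethod
    def from_jsonl(cls, text: str) -> "SessionLog":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValueError("empty log")
        head = json.loads(lines[0])
        if head.get("type") != "header":
            raise ValueError("first log line is not a header")
        head.pop("type")
        return cls(header=head, events=[json.loads(ln) for ln in lines[1:]])


@dataclass
class SessionState:
    config: TaskConfig
    plan: list[TrialPlan]
    current_trial: int
    current_step: int
    phase: SessionPhase
    log: SessionLog
    last_display_ts: int = 0
    last_event_ts: int = 0


# --------------------------------------------------------------------------
# Trial generation
# --------------------------------------------------------------------------

def _trial_rng(seed: int, trial_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed, trial_index]))


def generate_trial_plan(
    config: TaskConfig,
    trial_index: int,
    valence: Valence,
    rng: Optional[np.random.Generator] = None,
) -> TrialPlan:
    """Draw the (stimulus, location) sequence for one trial.

    Locations are sampled uniformly without replacement from the grid, so all
    ``max_items`` locations are pairwise distinct.  Stimuli come from the
    subset of the stimulus set matching ``valence``: with ``stimulus_choice =
    random`` they are drawn uniformly (without replacement in the varied
    condition); with ``defined`` they are taken in listed order.

    If *rng* is omitted it is derived from ``(config.rng_seed, trial_index)``,
    making the plan a pure function of config and trial index.
    """
    if rng is None:
        rng = _trial_rng(config.rng_seed, trial_index)
    subset = config.stimuli_with_valence(valence)
    if not subset:
        raise EngineError(f"no stimuli with valence {valence.value!r} in stimulus_set")

    k = config.max_items
    locations = rng.choice(config.grid.n_locations, size=k, replace=False)

    if config.condition is Condition.unique:
        if config.stimulus_choice is StimulusChoice.random:
            stim = subset[int(rng.integers(len(subset)))]
        else:
            stim = subset[0]
        chosen = [stim] * k
    else:
        if len(subset) < k:
            raise EngineError(
                f"varied condition needs {k} distinct stimuli with valence "
                f"{valence.value!r}, got {len(subset)}"
            )
        if config.stimulus_choice is StimulusChoice.random:
            idx = rng.choice(len(subset), size=k, replace=False)
            chosen = [subset[int(i)] for i in idx]
        else:
            chosen = subset[:k]

    categories = {s.category.value for s in chosen}
    return TrialPlan(
        trial_index=trial_index,
        items=tuple((s.stimulus_id, int(loc)) for s, loc in zip(chosen, locations)),
        condition=config.condition,
        valence=valence,
        category=categories.pop() if len(categories) == 1 else "mixed",
    )


def _valence_sequence(config: TaskConfig) -> list[Valence]:
    """Per-trial valences: the configured counts (or an even split across the
    valences present in the stimulus set), interleaved by a deterministic
    shuffle from the config seed."""
    if config.trials_per_valence is not None:
        counts = [(v, config.trials_per_valence[v])
                  for v in Valence if v in config.trials_per_valence]
    else:
        present = [v for v in Valence if config.stimuli_with_valence(v)]
        base, extra = divmod(config.n_trials, len(present))
        counts = [(v, base + (1 if i < extra else 0)) for i, v in enumerate(present)]
    seq: list[Valence] = []
    for v, n in counts:
        seq.extend([v] * n)
    order_rng = np.random.default_rng(np.random.SeedSequence([config.rng_seed, _ORDER_STREAM]))
    perm = order_rng.permutation(len(seq))
    return [seq[int(i)] for i in perm]


# --------------------------------------------------------------------------
# Session state machine
# --------------------------------------------------------------------------

def start_session(config: TaskConfig, metadata: Optional[dict[str, Any]] = None) -> SessionState:
    """Pre-draw all trial plans and open the session at trial 0, step 1.

    *metadata* (e.g. participant demographics) is stored verbatim in the log
    header.
    """
    valences = _valence_sequence(config)
    plans = [generate_trial_plan(config, i, v) for i, v in enumerate(valences)]
    header: dict[str, Any] = {
        "config": json.loads(config.model_dump_json()),
        "metadata": metadata or {},
    }
    state = SessionState(
        config=config,
        plan=plans,
        current_trial=0,
        current_step=1,
        phase=SessionPhase.awaiting_response,
        log=SessionLog(header=header),
    )
    _log_display(state, timestamp_ms=0)
    return state


def current_display(state: SessionState) -> DisplaySpec:
    """The on-screen array for the current step (pure; stable across calls)."""
    if state.phase is not SessionPhase.awaiting_response:
        raise StateError(f"no display in phase {state.phase.value}")
    plan = state.plan[state.current_trial]
    k = state.current_step
    visible = plan.items[:k]
    return DisplaySpec(step=k, visible=visible, target_location=visible[-1][1])


def _log_display(state: SessionState, timestamp_ms: int) -> None:
    disp = current_display(state)
    state.last_display_ts = timestamp_ms
    state.last_event_ts = timestamp_ms
    state.log.append({
        "type": "display",
        "timestamp_ms": timestamp_ms,
        "trial_index": state.current_trial,
        "step": disp.step,
        "visible": [list(item) for item in disp.visible],
        "target_location": disp.target_location,
    })


def _feedback(config: TaskConfig, correct: bool) -> FeedbackEvent:
    mode = config.feedback_mode
    if mode is FeedbackMode.none:
        return FeedbackEvent(FeedbackKind.none)
    if not correct:
        return FeedbackEvent(FeedbackKind.wrong_tone)
    if mode is FeedbackMode.auditory_plus_reward:
        return FeedbackEvent(FeedbackKind.reward)
    return FeedbackEvent(FeedbackKind.correct_tone)


def apply_response(
    state: SessionState, response: ResponseEvent
) -> tuple[SessionState, FeedbackEvent, bool]:
    """Apply one touch: advance on a correct choice, end the trial on a
    mistake or at the item ceiling.

    A touch on a location with no visible stimulus is logged as an
    ``invalid_touch`` event and raises :class:`InvalidResponseError`; the
    session state is unchanged and the touch does not count as a response.
    """
    if state.phase is not SessionPhase.awaiting_response:
        raise StateError(f"cannot respond in phase {state.phase.value}")
    ts = int(response.timestamp_ms)
    if ts < state.last_event_ts:
        raise StateError(
            f"non-monotone timestamp {ts} < {state.last_event_ts}")
    plan = state.plan[state.current_trial]
    k = state.current_step
    visible_locs = [loc for _, loc in plan.items[:k]]
    if response.chosen_location not in visible_locs:
        state.log.append({
            "type": "invalid_touch",
            "timestamp_ms": ts,
            "trial_index": state.current_trial,
            "step": k,
            "chosen_location": response.chosen_location,
        })
        state.last_event_ts = ts
        raise InvalidResponseError(
            f"location {response.chosen_location} is not visible at step {k}")

    target = visible_locs[-1]
    correct = response.chosen_location == target
    state.last_event_ts = ts
    state.log.append({
        "type": "response",
        "timestamp_ms": ts,
        "trial_index": state.current_trial,
        "step": k,
        "chosen_location": int(response.chosen_location),
        "correct": correct,
    })
    fb = _feedback(state.config, correct)
    if fb.kind is not FeedbackKind.none:
        state.log.append({
            "type": "feedback",
            "timestamp_ms": ts,
            "trial_index": state.current_trial,
            "kind": fb.kind.value,
        })

    if correct and k < state.config.max_items:
        state.current_step = k + 1
        _log_display(state, timestamp_ms=ts + state.config.interval_time_ms)
    else:
        span = k if correct else k - 1
        state.phase = SessionPhase.trial_ended
        state.log.append({
            "type": "trial_end",
            "timestamp_ms": ts,
            "trial_index": state.current_trial,
            "condition": plan.condition.value,
            "valence": plan.valence.value,
            "category": plan.category,
            "span": span,
            "ended_by": "ceiling" if correct else "mistake",
        })
    return state, fb, correct


def advance_trial(state: SessionState) -> SessionState:
    """Move to the next trial (step 1), or close the session after the last."""
    if state.phase is not SessionPhase.trial_ended:
        raise StateError(f"cannot advance trial in phase {state.phase.value}")
    if state.current_trial + 1 >= len(state.plan):
        state.phase = SessionPhase.session_ended
        state.log.append({
            "type": "session_end",
            "timestamp_ms": state.last_event_ts,
            "n_trials": len(state.plan),
        })
        return state
    state.current_trial += 1
    state.current_step = 1
    state.phase = SessionPhase.awaiting_response
    _log_display(state, timestamp_ms=state.last_event_ts + state.config.interval_time_ms)
    return state


# --------------------------------------------------------------------------
# Agent harness
# --------------------------------------------------------------------------

class AgentProtocol(Protocol):
    """Choice contract for simulated participants (see :mod:`sdrst.agents`)."""

    def describe(self) -> dict[str, Any]: ...
    def begin_trial(self) -> None: ...
    def choose(self, display: DisplaySpec, rng: np.random.Generator) -> int: ...
    def observe_outcome(self, target_location: int) -> None: ...
    def response_time_ms(self, rng: np.random.Generator) -> int: ...


def run_with_agent(
    config: TaskConfig,
    agent: AgentProtocol,
    agent_seed: int,
    metadata: Optional[dict[str, Any]] = None,
) -> SessionLog:
    """Run a full session with a simulated participant; returns the complete log.

    The agent sees each :class:`DisplaySpec`, returns a touched location, and
    after every response is told the true target location (the task's
    feedback — advance or trial end — reveals it).  ``(config.rng_seed,
    agent_seed)`` fully determine the log, byte for byte.
    """
    state = start_session(config, metadata=metadata)
    state.log.header["agent"] = agent.describe()
    state.log.header["agent_seed"] = int(agent_seed)
    rng = np.random.default_rng(np.random.SeedSequence([int(agent_seed)]))
    while state.phase is not SessionPhase.session_ended:
        if state.current_step == 1:
            agent.begin_trial()
        disp = current_display(state)
        loc = agent.choose(disp, rng)
        ts = state.last_display_ts + agent.response_time_ms(rng)
        _, _, _ = apply_response(state, ResponseEvent(chosen_location=loc, timestamp_ms=ts))
        agent.observe_outcome(disp.target_location)
        if state.phase is SessionPhase.trial_ended:
            advance_trial(state)
    return state.log


def iter_trial_events(log: SessionLog) -> Iterable[list[dict[str, Any]]]:
    """Group a session's events by trial, in order (helper for scoring/replay)."""
    current: list[dict[str, Any]] = []
    for ev in log.events:
        if ev["type"] == "session_end":
            break
        current.append(ev)
        if ev["type"] == "trial_end":
            yield current
            current = []
    if current:
        yield current
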