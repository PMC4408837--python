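"""Simulated participants for the SDRST.

Two behavioural models make the task runnable end-to-end without a human:

* a **chance agent** that touches a uniformly random visible stimulus — its
  mean span has the closed form ``sum_{k=1}^{max_items} 1/k!`` and serves as
  the chance line against which performance is judged;
* a **capacity agent**, a parametric stand-in for working-memory load: it
  retains the ``m`` most recent old locations (FIFO eviction, a recency
  model) and, unless it lapses (probability ``eps``), touches a uniformly
  random visible location *not* in memory.  After each response the true
  novel location is pushed into memory regardless of the choice made — the
  task's corrective structure (advance vs. trial end) reveals it.

With ``m = 0, eps = 0`` the capacity agent is distributionally identical to
the chance agent; with ``m >= max_items - 1, eps = 0`` it is a perfect
responder (span = ceiling on every trial).  Because memory always holds true
past targets, the probability of a correct touch at step ``k`` is exact:

    p_k = eps / k + (1 - eps) / (k - min(m, k - 1))

and the expected span is the survival sum ``sum_j prod_{k<=j} p_k``, computed
by :func:`expected_capacity_span` by enumerating step outcomes.

Synthetic response latencies are lognormal with a configured mean/sd (moment
matched), floored at 1 ms so they are strictly positive.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .engine import DisplaySpec


@dataclass(frozen=True)
class AgentParams:
    """Capacity ``m`` (old locations retained), lapse rate ``eps`` in [0, 1],
    and the (mean, sd) of the lognormal response-time model in ms."""

    m: int = 0
    eps: float = 0.0
    rt_mean_ms: float = 800.0
    rt_sd_ms: float = 250.0

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError("capacity m must be non-negative")
        if not 0.0 <= self.eps <= 1.0:
            raise ValueError("lapse rate eps must lie in [0, 1]")
        if self.rt_mean_ms < 0 or self.rt_sd_ms < 0:
            raise ValueError("response-time mean and sd must be non-negative")


@dataclass
class AgentState:
    """The capacity agent's memory: at most ``m`` locations, most recent last."""

    m: int
    remembered_locations: deque[int] = field(default_factory=deque)

    def reset(self) -> None:
        self.remembered_locations.clear()

    def push(self, location: int) -> None:
        self.remembered_locations.append(location)
        while len(self.remembered_locations) > self.m:
            self.remembered_locations.popleft()


# --------------------------------------------------------------------------
# Choice rules (pure functions)
# --------------------------------------------------------------------------

def random_choice(display: DisplaySpec, rng: np.random.Generator) -> int:
    """Uniform draw over the visible locations (the chance baseline)."""
    locs = display.visible_locations
    if not locs:
        raise ValueError("display has no visible stimuli")
    return locs[int(rng.integers(len(locs)))]


def capacity_choice(
    params: AgentParams,
    state: AgentState,
    display: DisplaySpec,
    rng: np.random.Generator,
) -> tuple[int, AgentState]:
    """One capacity-limited choice; updates memory with the true target.

    With probability ``eps`` the choice is uniform over all visible locations
    (a lapse); otherwise it is uniform over visible locations not currently
    remembered.  The true novel location is then pushed into memory, evicting
    the oldest entry beyond capacity.
    """
    locs = display.visible_locations
    if not locs:
        raise ValueError("display has no visible stimuli")
    if params.eps > 0 and rng.random() < params.eps:
        chosen = locs[int(rng.integers(len(locs)))]
    else:
        remembered = state.remembered_locations
        candidates = [l for l in locs if l not in remembered]
        if not candidates:  # cannot happen when memory holds only old locations
            candidates = list(locs)
        chosen = candidates[int(rng.integers(len(candidates)))]
    state.push(display.target_location)
    return chosen, state


# --------------------------------------------------------------------------
# Exact expectations
# --------------------------------------------------------------------------

def expected_random_span(max_items: int) -> float:
    """Closed-form mean span of the chance agent: ``sum_{k=1}^{max_items} 1/k!``.

    At step ``k`` there are ``k`` visible stimuli and chance success is
    ``1/k``, so P(span >= j) = 1/j! and the expectation telescopes to the
    partial sum of reciprocal factorials (about 1.71828 for the standard
    ceiling of 8 items, i.e. e - 1 truncated at 8 terms).
    """
    if max_items < 1:
        raise ValueError("max_items must be >= 1")
    return sum(1.0 / math.factorial(k) for k in range(1, max_items + 1))


def capacity_step_probabilities(m: int, eps: float, max_items: int) -> list[float]:
    """Exact per-step correct-touch probabilities for the capacity agent.

    At step ``k`` memory holds ``min(m, k - 1)`` of the ``k - 1`` old
    locations (the most recent true targets, all distinct), so a non-lapse
    choice is uniform over ``k - min(m, k - 1)`` unremembered locations, one
    of which is the target.
    """
    if max_items < 1:
        raise ValueError("max_items must be >= 1")
    probs = []
    for k in range(1, max_items + 1):
        held = min(m, k - 1)
        probs.append(eps / k + (1.0 - eps) / (k - held))
    return probs


def expected_capacity_span(m: int, eps: float, max_items: int) -> float:
    """Exact mean span of the capacity agent by enumeration of step outcomes.

    The trial survives step ``k`` with probability ``p_k`` independently of
    earlier steps (memory content at step ``k`` is deterministic given the
    trial reached it), so E[span] = sum_j prod_{k<=j} p_k.
    """
    probs = capacity_step_probabilities(m, eps, max_items)
    expect, survive = 0.0, 1.0
    for p in probs:
        survive *= p
        expect += survive
    return expect


# --------------------------------------------------------------------------
# Agent classes (engine choice contract)
# --------------------------------------------------------------------------

class _BaseAgent:
    def __init__(self, params: AgentParams):
        self.params = params
        if params.rt_mean_ms > 0 and params.rt_sd_ms > 0:
            s2 = math.log(1.0 + (params.rt_sd_ms / params.rt_mean_ms) ** 2)
            self._rt_mu = math.log(params.rt_mean_ms) - s2 / 2.0
            self._rt_sigma = math.sqrt(s2)
        else:
            self._rt_mu = None
            self._rt_sigma = 0.0

    def begin_trial(self) -> None:
        pass

    def observe_outcome(self, target_location: int) -> None:
        pass

    def response_time_ms(self, rng: np.random.Generator) -> int:
        if self._rt_mu is None:
            return max(1, int(round(self.params.rt_mean_ms)))
        rt = rng.lognormal(self._rt_mu, self._rt_sigma)
        return max(1, int(round(rt)))

    def describe(self) -> dict[str, Any]:
        raise NotImplementedError


class RandomAgent(_BaseAgent):
    """The chance agent: uniform over visible stimuli, no memory."""

    def __init__(self, params: AgentParams | None = None):
        super().__init__(params or AgentParams())

    def choose(self, display: DisplaySpec, rng: np.random.Generator) -> int:
        return random_choice(display, rng)

    def describe(self) -> dict[str, Any]:
        return {"name": "random",
                "rt_mean_ms": self.params.rt_mean_ms, "rt_sd_ms": self.params.rt_sd_ms}


class CapacityAgent(_BaseAgent):
    """Capacity-``m``, lapse-``eps`` working-memory agent (FIFO recency memory)."""

    def __init__(self, params: AgentParams):
        super().__init__(params)
        self.state = AgentState(m=params.m)

    def begin_trial(self) -> None:
        self.state.reset()

    def choose(self, display: DisplaySpec, rng: np.random.Generator) -> int:
        # capacity_choice also pushes the true target (display carries it),
        # so observe_outcome needs no further update
        chosen, self.state = capacity_choice(self.params, self.state, display, rng)
        return chosen

    def describe(self) -> dict[str, Any]:
        return {"name": "capacity", "m": self.params.m, "eps": self.params.eps,
                "rt_mean_ms": self.params.rt_mean_ms, "rt_sd_ms": self.params.rt_sd_ms}


class PerfectAgent(_BaseAgent):
    """Always touches the novel location — the span-ceiling reference."""

    def __init__(self, params: AgentParams | None = None):
        super().__init__(params or AgentParams())

    def choose(self, display: DisplaySpec, rng: np.random.Generator) -> int:
        return display.target_location

    def describe(self) -> dict[str, Any]:
        return {"name": "perfect",
                "rt_mean_ms": self.params.rt_mean_ms, "rt_sd_ms": self.params.rt_sd_ms}


def make_agent(name: str, **params: float) -> _BaseAgent:
    """Build an agent by CLI name (``random``, ``capacity``, ``perfect``).

    Keyword parameters map onto :class:`AgentParams` fields; ``m`` and ``eps``
    are meaningful only for the capacity agent.
    """
    ap = AgentParams(
        m=int(params.pop("m", 0)),
        eps=float(params.pop("eps", 0.0)),
        rt_mean_ms=float(params.pop("rt_mean_ms", 800.0)),
        rt_sd_ms=float(params.pop("rt_sd_ms", 250.0)),
    )
    if params:
        raise ValueError(f"unknown agent parameter(s): {sorted(params)}")
    if name == "random":
        return RandomAgent(ap)
    if name == "capacity":
        return CapacityAgent(ap)
    if name == "perfect":
        return PerfectAgent(ap)
    raise ValueError(f"unknown agent {name!r}; expected random, capacity or perfect")
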