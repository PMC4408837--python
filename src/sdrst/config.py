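"""Task configuration for the Spatial Delayed Recognition Span Task (SDRST).

The SDRST presents stimuli one at a time on a touch grid; at each step the
participant must touch the stimulus occupying a *new* location among a growing
array.  This module defines the full examiner-facing parameter surface of the
task — stimulus set, unique/varied condition, grid geometry, timing, feedback
mode, trial counts per emotional valence — together with JSON (de)serialisation
and the parameterisations of the three published validation studies.

Stimuli are abstract identifiers with category/valence metadata; no image
assets are managed here.  All times are integer milliseconds; physical sizes
in cm are metadata only (the engine is headless and never renders).
"""

from __future__ import annotations

import enum
import json
from typing import Optional

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class StimulusCategory(str, enum.Enum):
    geometric = "geometric"
    iaps_scene = "iaps_scene"
    face = "face"


class Valence(str, enum.Enum):
    negative = "negative"
    positive = "positive"
    neutral = "neutral"
    none = "none"


class Condition(str, enum.Enum):
    """Within-trial stimulus identity: ``unique`` repeats one image for every
    item of a trial (location is the only cue); ``varied`` gives each item a
    different image (identity is an extra mnemonic cue)."""

    unique = "unique"
    varied = "varied"


class StimulusChoice(str, enum.Enum):
    random = "random"
    defined = "defined"


class FeedbackMode(str, enum.Enum):
    none = "none"
    auditory = "auditory"
    auditory_plus_reward = "auditory_plus_reward"


class ConfigError(ValueError):
    """Raised when a task configuration violates a task invariant."""


class StimulusSpec(BaseModel):
    """One abstract stimulus: an opaque id plus display metadata."""

    model_config = ConfigDict(frozen=True)

    stimulus_id: str = Field(min_length=1)
    category: StimulusCategory
    valence: Valence = Valence.none
    display_size_cm: tuple[float, float] = (4.0, 4.0)

    @field_validator("display_size_cm")
    @classmethod
    def _positive_size(cls, v: tuple[float, float]) -> tuple[float, float]:
        if v[0] <= 0 or v[1] <= 0:
            raise ValueError("display_size_cm: both dimensions must be positive")
        return v

    @model_validator(mode="after")
    def _valence_category(self) -> "StimulusSpec":
        if self.valence is Valence.none and self.category is not StimulusCategory.geometric:
            raise ValueError(
                "valence: 'none' is permitted only for geometric stimuli "
                f"(stimulus {self.stimulus_id!r} has category {self.category.value})"
            )
        return self


def _regular_grid(n_rows: int, n_cols: int) -> list[tuple[float, float]]:
    """Evenly spaced cell centres on the unit square, row-major order."""
    return [
        (round((c + 0.5) / n_cols, 9), round((r + 0.5) / n_rows, 9))
        for r in range(n_rows)
        for c in range(n_cols)
    ]


class GridSpec(BaseModel):
    """The response grid: ``n_rows x n_cols`` abstract touch locations.

    The default is a 4x4 grid of 16 evenly spaced cells on the unit square,
    the simplest symmetric arrangement of 16 possible locations.  Coordinates
    are abstract (no pixel geometry); a touch is resolved by cell index.
    """

    model_config = ConfigDict(frozen=True)

    n_rows: int = Field(default=4, ge=1)
    n_cols: int = Field(default=4, ge=1)
    cell_positions: Optional[list[tuple[float, float]]] = None

    @model_validator(mode="after")
    def _fill_and_check(self) -> "GridSpec":
        if self.cell_positions is None:
            object.__setattr__(self, "cell_positions", _regular_grid(self.n_rows, self.n_cols))
        if len(self.cell_positions) != self.n_rows * self.n_cols:
            raise ValueError(
                "cell_positions: expected "
                f"{self.n_rows * self.n_cols} positions, got {len(self.cell_positions)}"
            )
        if len(set(self.cell_positions)) != len(self.cell_positions):
            raise ValueError("cell_positions: positions must be pairwise distinct")
        return self

    @property
    def n_locations(self) -> int:
        return self.n_rows * self.n_cols


class TaskConfig(BaseModel):
    """Every examiner-selectable parameter of one SDRST session.

    ``max_items`` is the span ceiling: the array grows by one stimulus per
    correct response up to this many items.  ``exposure_time_ms`` and
    ``delay_time_ms`` are stored and logged verbatim; only
    ``interval_time_ms`` (the pause between a response and the next display)
    enters the engine's synthetic event timing.
    """

    model_config = ConfigDict(frozen=True)

    stimulus_set: list[StimulusSpec] = Field(min_length=1)
    condition: Condition = Condition.unique
    stimulus_choice: StimulusChoice = StimulusChoice.random
    n_trials: int = Field(ge=1)
    max_items: int = Field(default=8, ge=1)
    grid: GridSpec = Field(default_factory=GridSpec)
    exposure_time_ms: int = Field(default=1000, ge=0)
    delay_time_ms: int = Field(default=0, ge=0)
    interval_time_ms: int = Field(default=1000, ge=0)
    background_color: str = "black"
    feedback_mode: FeedbackMode = FeedbackMode.none
    trials_per_valence: Optional[dict[Valence, int]] = None
    rng_seed: int = Field(default=0, ge=0, lt=2**63)

    @model_validator(mode="after")
    def _invariants(self) -> "TaskConfig":
        ids = [s.stimulus_id for s in self.stimulus_set]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"stimulus_set: duplicate stimulus_id(s) {dup}")
        if self.max_items > self.grid.n_locations:
            raise ValueError(
                f"max_items: {self.max_items} stimuli cannot be placed on "
                f"{self.grid.n_locations} grid locations"
            )
        if self.condition is Condition.varied and len(self.stimulus_set) < self.max_items:
            raise ValueError(
                "stimulus_set: varied condition needs at least max_items "
                f"(={self.max_items}) distinct stimuli, got {len(self.stimulus_set)}"
            )
        if self.trials_per_valence is not None:
            if any(n < 0 for n in self.trials_per_valence.values()):
                raise ValueError("trials_per_valence: counts must be non-negative")
            total = sum(self.trials_per_valence.values())
            if total != self.n_trials:
                raise ValueError(
                    f"trials_per_valence: counts sum to {total}, expected n_trials={self.n_trials}"
                )
        return self

    def with_updates(self, **updates) -> "TaskConfig":
        """A copy with fields replaced, re-run through full validation."""
        data = self.model_dump()
        data.update(updates)
        return TaskConfig.model_validate(data)

    def stimuli_with_valence(self, valence: Valence) -> list[StimulusSpec]:
        return [s for s in self.stimulus_set if s.valence is valence]


def load_config(serialized: str) -> TaskConfig:
    """Parse a JSON task configuration, filling defaults and checking invariants.

    Raises :class:`ConfigError` on malformed JSON or any invariant violation;
    the message names the offending field.
    """
    try:
        data = json.loads(serialized)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"malformed JSON: {exc}") from exc
    try:
        return TaskConfig.model_validate(data)
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def save_config(config: TaskConfig) -> str:
    """Serialise to canonical JSON (sorted keys, 2-space indent, UTF-8 safe).

    ``load_config(save_config(c)) == c`` and re-saving reproduces the text
    bit-identically.
    """
    data = config.model_dump(mode="json")
    return json.dumps(data, sort_keys=True, indent=2, ensure_ascii=False) + "\n"


# --------------------------------------------------------------------------
# Study presets
# --------------------------------------------------------------------------

def _stimuli(category: StimulusCategory, valence: Valence, prefix: str, n: int) -> list[StimulusSpec]:
    return [
        StimulusSpec(stimulus_id=f"{prefix}_{valence.value}_{i:02d}", category=category, valence=valence)
        for i in range(1, n + 1)
    ]


def _geometric(n: int) -> list[StimulusSpec]:
    return [
        StimulusSpec(stimulus_id=f"geo_{i:02d}", category=StimulusCategory.geometric, valence=Valence.none)
        for i in range(1, n + 1)
    ]


_EMOTIONAL = (Valence.negative, Valence.positive, Valence.neutral)


def preset(name: str) -> TaskConfig:
    """Parameterisation of one of the three published validation studies.

    ========  =============================  ==========  ==================
    preset    stimuli                        interval    trials per valence
    ========  =============================  ==========  ==================
    study_a   IAPS scenes + geometric        5000 ms     16 (64 trials)
    study_b   faces + geometric, auditory    3000 ms     10 (40 trials)
              feedback
    study_c   IAPS scenes + geometric        1000 ms     16 (64 trials)
    ========  =============================  ==========  ==================

    All three use the 4x4 grid (16 locations) and a span ceiling of 8 items.
    Stimulus ids are abstract placeholders (8 per valence, enough for the
    varied condition); the published image assets are not shipped.
    """
    presets = {"study_a": 5000, "study_b": 3000, "study_c": 1000}
    if name not in presets:
        raise ConfigError(f"unknown preset {name!r}; expected one of {sorted(presets)}")

    if name == "study_b":
        emotional_cat, prefix, per_valence, feedback = (
            StimulusCategory.face, "face", 10, FeedbackMode.auditory)
    else:
        emotional_cat, prefix, per_valence, feedback = (
            StimulusCategory.iaps_scene, "iaps", 16, FeedbackMode.none)

    stimulus_set: list[StimulusSpec] = []
    for v in _EMOTIONAL:
        stimulus_set.extend(_stimuli(emotional_cat, v, prefix, 8))
    stimulus_set.extend(_geometric(8))

    tpv = {v: per_valence for v in _EMOTIONAL}
    tpv[Valence.none] = per_valence
    return TaskConfig(
        stimulus_set=stimulus_set,
        condition=Condition.unique,
        stimulus_choice=StimulusChoice.random,
        n_trials=4 * per_valence,
        max_items=8,
        grid=GridSpec(n_rows=4, n_cols=4),
        interval_time_ms=presets[name],
        feedback_mode=feedback,
        trials_per_valence=tpv,
        rng_seed=0,
    )
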