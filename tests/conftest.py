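import pytest
from hypothesis import HealthCheck, settings

from sdrst import (
    GridSpec,
    RandomAgent,
    StimulusCategory,
    StimulusSpec,
    TaskConfig,
    Valence,
    preset,
    run_with_agent,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def geometric_stimuli(n: int) -> list[StimulusSpec]:
    return [
        StimulusSpec(stimulus_id=f"g{i}", category=StimulusCategory.geometric,
                     valence=Valence.none)
        for i in range(n)
    ]


@pytest.fixture
def minimal_config() -> TaskConfig:
    """Smallest legal task: one geometric stimulus, unique condition."""
    return TaskConfig(stimulus_set=geometric_stimuli(1), n_trials=4, rng_seed=11)


@pytest.fixture
def varied_config() -> TaskConfig:
    return TaskConfig(stimulus_set=geometric_stimuli(10), condition="varied",
                      n_trials=6, rng_seed=5)


@pytest.fixture(scope="session")
def study_b_random_log():
    """One full study-b session played by the chance agent."""
    return run_with_agent(preset("study_b"), RandomAgent(), agent_seed=42)
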