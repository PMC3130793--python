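"""Shared fixtures: simulated experiments reused across test modules."""

import pytest
from hypothesis import settings

from phytocosm import ExperimentConfig, simulate_experiment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def default_result():
    """One default-configuration simulation (with counting noise)."""
    return simulate_experiment(ExperimentConfig(), seed=11)


@pytest.fixture(scope="session")
def noisefree_result():
    """Default simulation with the observation model disabled."""
    from phytocosm import ObservationModel

    cfg = ExperimentConfig(observation=ObservationModel(enabled=False))
    return simulate_experiment(cfg, seed=11)
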