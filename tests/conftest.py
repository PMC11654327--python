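import numpy as np
import pytest
from hypothesis import settings

from vescasim import SimulationParams, run_condition
from vescasim.cli_io import make_fixture

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_params():
    return SimulationParams()


@pytest.fixture(scope="session")
def tiny_connected():
    return make_fixture("tiny-connected", seed=7)


@pytest.fixture(scope="session")
def tiny_disconnected():
    return make_fixture("tiny-disconnected", seed=7)


@pytest.fixture(scope="session")
def two_cohort_shift():
    return make_fixture("two-cohort-shift", seed=4)


class ConditionCache:
    """Runs each Monte-Carlo condition once per test session."""

    def __init__(self):
        self._store = {}

    def get(self, params: SimulationParams, n_replicates: int = 200, seed: int = 1,
            accuracy: bool = False):
        key = (params, n_replicates, seed)
        if key not in self._store:
            self._store[key] = run_condition(
                params, n_replicates, seed, return_accuracy=True
            )
        summary, acc = self._store[key]
        return (summary, acc) if accuracy else summary


@pytest.fixture(scope="session")
def conditions():
    return ConditionCache()
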