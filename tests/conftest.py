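import numpy as np
import pytest

from igtsim import AgentParams, default_task


@pytest.fixture(scope="session")
def task():
    return default_task()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def learner_params():
    """High-memory, loss-sensitive, gain-insensitive agent."""
    return AgentParams(memory=0.9, gain_sensitivity=0.1, loss_sensitivity=0.5)
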