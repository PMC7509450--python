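import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_params():
    from ca1ach.params import ModelParams
    return ModelParams()


@pytest.fixture(scope="session")
def model(default_params):
    """The shipped calibrated model, assembled once per session."""
    from ca1ach.core import AssembledModel
    return AssembledModel(default_params)


@pytest.fixture(scope="session")
def rest(model):
    from ca1ach.protocols import rest_state
    return rest_state(model)


@pytest.fixture(scope="session")
def passive_params():
    """Electrical-only passive membrane: every active density zeroed."""
    from ca1ach.params import ModelParams
    p = ModelParams()
    for sec in (p.morphology.soma, p.morphology.trunk, p.morphology.axon):
        for ch in sec.channels:
            sec.channels[ch] = 0.0 if ch != "leak" else 0.25
    return p
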