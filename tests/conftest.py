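import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def broken_params():
    from brokenduet import LorenzParameters

    return LorenzParameters.broken()


@pytest.fixture(scope="session")
def broken_trajectory(broken_params):
    """A moderately long broken-regime trajectory from the speaker's init."""
    from brokenduet import integrate

    return integrate((0.8, -3.0, 0.0), broken_params, n_steps=1023)


@pytest.fixture(scope="session")
def matched_percept(broken_trajectory):
    """Percept generated from the listener's own observation map (lobe +1)."""
    w = 0.5 * np.tanh(1.0)
    return w * broken_trajectory.y + broken_trajectory.z


@pytest.fixture(scope="session")
def listener_spec_a():
    from brokenduet import PrecisionConfig, build_listener_model

    return build_listener_model(PrecisionConfig.A())
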