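import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def ustulata_params():
    """A typical diploid tube: 2C 10.46 pg, P 3.53 pg vs. the 2.57 pg standard."""
    from peflow import SOLANUM, SimulationParams

    return SimulationParams(
        two_c_pg=10.46, p_pg=3.53, standard=SOLANUM, seed=42
    )


@pytest.fixture
def ustulata_events(ustulata_params):
    from peflow import simulate_sample

    return simulate_sample(ustulata_params)
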