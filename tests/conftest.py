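import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mirstruct.energy import EnergyModel

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def model() -> EnergyModel:
    return EnergyModel()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_rna(rng, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))
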