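import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitoswitch import ModelParameters

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def defaults() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_valid_states(params: ModelParameters, n: int,
                        seed: int = 7) -> np.ndarray:
    """Uniform samples inside the admissible state box."""
    from mitoswitch.model import state_bounds

    lo, hi = state_bounds(params)
    gen = np.random.default_rng(seed)
    return lo + (hi - lo) * gen.random((n, 6))
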