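import numpy as np
import pytest

from plaidswitch import ModelParameters


@pytest.fixture(scope="session")
def base_params() -> ModelParameters:
    """Reference operating point of the sweep battery."""
    return ModelParameters.sweep_base()


@pytest.fixture(scope="session")
def short_params(base_params) -> ModelParameters:
    """Cheap 10-s trial for unit tests."""
    return base_params.with_updates(duration=10.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
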