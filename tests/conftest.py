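import numpy as np
import pytest

from hpatoggle import ModelParameters, SystemState
from hpatoggle.scenarios import simplified_fixed_state


@pytest.fixture(scope="session")
def nominal() -> ModelParameters:
    return ModelParameters()


@pytest.fixture(scope="session")
def euthymic_state(nominal) -> SystemState:
    return simplified_fixed_state("euthymic", 1.0, 1.0, nominal)


@pytest.fixture(scope="session")
def depressed_state(nominal) -> SystemState:
    return simplified_fixed_state("depressed", 1.0, 1.0, nominal)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
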