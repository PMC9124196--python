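import numpy as np
import pytest

from dcisim.params import ParameterSet


@pytest.fixture(scope="session")
def baseline() -> ParameterSet:
    return ParameterSet().validate()


@pytest.fixture(scope="session")
def tiny_params() -> ParameterSet:
    """A miniature duct for fast engine-level tests."""
    return ParameterSet(duct_length=200.0, duct_inner_diameter=60.0,
                        grid_h=10.0)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
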