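import numpy as np
import pytest
from hypothesis import settings

from metaloop.parameters import ParameterEntry, ParameterSpec

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def scalar_spec():
    return ParameterSpec((ParameterEntry("x", 1, 0.0, 1.0),))


@pytest.fixture
def small_spec():
    return ParameterSpec((
        ParameterEntry("w", 3, -1.0, 1.0),
        ParameterEntry("d", 2, 1.0, 6.0, kind="integer"),
    ))
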