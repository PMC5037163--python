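import numpy as np
import pytest
from hypothesis import settings

from emcoloc import EXAMPLE_BAND, worked_example_fixture

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")


@pytest.fixture
def example_stack():
    """The packaged single-image worked example."""
    return worked_example_fixture()


@pytest.fixture
def example_band():
    return EXAMPLE_BAND


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
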