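import numpy as np
import pytest

from qclsim import TOMATO_FIRMNESS, MonitorConfig, ScalarField, table3_scenario


@pytest.fixture
def tomato():
    return TOMATO_FIRMNESS


@pytest.fixture
def mconfig():
    return MonitorConfig()


@pytest.fixture
def scenario():
    """Fresh reference scenario per test (the pipeline mutates pallets)."""
    return table3_scenario()


@pytest.fixture
def random_field():
    """A seeded, fully-populated 5x5 temperature field around room mean."""
    rng = np.random.default_rng(42)
    return ScalarField(rng.uniform(18.0, 26.0, (5, 5)), np.ones((5, 5), bool))
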