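import numpy as np
import pytest

from phenoscan import default_presets, make_layout, simulate_plate
from phenoscan.pipeline import measure_plate_set


@pytest.fixture(scope="session")
def presets():
    return default_presets()


@pytest.fixture(scope="session")
def small_layout():
    """One plate with 8 paraquat and 8 control wells."""
    return make_layout(4, 4, (500, 480), ["paraquat", "control"], seed=1)


@pytest.fixture(scope="session")
def plate_6hat(presets, small_layout):
    """Paraquat/control plate at 6 HAT, default noise."""
    return simulate_plate(small_layout, presets, 6, seed=101)


@pytest.fixture(scope="session")
def plate_3hat(presets, small_layout):
    return simulate_plate(small_layout, presets, 3, seed=102)


@pytest.fixture(scope="session")
def measured_6hat(plate_6hat):
    return measure_plate_set(plate_6hat)


@pytest.fixture(scope="session")
def measured_3hat(plate_3hat):
    return measure_plate_set(plate_3hat)


@pytest.fixture
def rng():
    return np.random.default_rng(42)
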