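import numpy as np
import pytest

from apopcal import GridSpec, ScaleVector, beat_trace
from apopcal.core import CONDUCTANCES

#: beat index far enough into pacing that the geometric transient (0.9^n)
#: is below double precision — a steady beat for all practical purposes
STEADY_BEAT = 500


@pytest.fixture(scope="session")
def control() -> ScaleVector:
    return ScaleVector()


@pytest.fixture(scope="session")
def steady_beat_400(control):
    return beat_trace(control, 400, STEADY_BEAT)


@pytest.fixture(scope="session")
def tiny_grid() -> GridSpec:
    """Two levels on every axis: 64 parameter sets."""
    return GridSpec(levels={name: (0.85, 1.15) for name in CONDUCTANCES})


@pytest.fixture(scope="session")
def three_level_grid() -> GridSpec:
    """Three levels on every axis: 729 parameter sets."""
    return GridSpec(levels={name: (0.85, 1.00, 1.15) for name in CONDUCTANCES})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20140228)
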