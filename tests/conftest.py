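import numpy as np
import pytest

from rbtransit.kinetics_sim import KineticParams
from rbtransit.synthetic_data import (Condition, TraceGenConfig,
                                      default_geometry)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def geometry():
    return default_geometry("opposing")


@pytest.fixture
def condition():
    return Condition(roadblock="LacI-O1", force_direction="opposing",
                     force_pN=0.2)


@pytest.fixture
def passive_params():
    """Pure-passive kinetics: transit only by roadblock dissociation."""
    return KineticParams(k1=0.0, k2=0.01, k3=0.01, p1=0.0)


@pytest.fixture
def quiet_gen():
    """Trace generator config without ubiquitous pauses or noise."""
    return TraceGenConfig(noise_sd=0.0, ubiquitous_pause_rate=0.0,
                          obs_window=600.0, seed=0)
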