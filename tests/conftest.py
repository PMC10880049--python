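import numpy as np
import pytest

from memclust import Configuration, HydroParams, SimParams


@pytest.fixture
def hydro():
    """Standard hydrodynamic parameters: eta_m = 4.5e-11 Pa s m,
    coarse-grained-water eta_w = 7e-4 Pa s, 300 K (SD length ~32 nm)."""
    return HydroParams(eta_m=4.5e-11, eta_w=7e-4, temperature=300.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_config(rng):
    def make(n=20, box=20.0):
        return Configuration(rng.uniform(0, box, size=(n, 2)), box)

    return make


@pytest.fixture
def fast_params():
    """Small, quick generator settings for structural/smoke tests."""
    return SimParams(n_inclusions=16, box_length=30.0, n_frames=51, seed=11)
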