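import numpy as np
import pytest
from hypothesis import settings

from chromem import DimensionlessParams, build_network

settings.register_profile("ci", max_examples=25, deadline=None,
                          derandomize=True)
settings.load_profile("ci")


@pytest.fixture
def base_params():
    """Symmetric unit parameters with basal inputs 0.1 (the standard
    no-external-input study condition)."""
    return DimensionlessParams(u0A=0.1, u10R=0.1, u20R=0.1, D_tot=50)


@pytest.fixture
def small_params():
    """Same regime at D_tot = 8, small enough for exact CME analysis."""
    return DimensionlessParams(u0A=0.1, u10R=0.1, u20R=0.1, D_tot=8)


@pytest.fixture
def full_net_small(small_params):
    return build_network(small_params)


def random_fraction_state(rng):
    x = rng.dirichlet(np.ones(5))
    return x  # order per CHROMATIN_SPECIES: D, DA, D1R, D2R, D12R
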