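import numpy as np
import pytest

from halfsarc import (ActivationParams, FilamentParams, GeometryConfig,
                      LatticeState, ModelParams, build_half_sarcomere)
from halfsarc.crossbridge_kinetics import RateParams, SpringParams
from halfsarc.mechanics import SolverConfig, TitinParams


@pytest.fixture
def springs():
    return SpringParams()


@pytest.fixture
def rates():
    return RateParams()


@pytest.fixture
def titin():
    return TitinParams()


@pytest.fixture
def model():
    return ModelParams()


@pytest.fixture
def small_geometry():
    """A reduced lattice (~4 crowns of overlap, 144 heads) for fast dynamics tests."""
    return GeometryConfig(crowns_per_thick=12, thin_sites_per_filament=7,
                          rest_hs_length=380.0)


@pytest.fixture
def small_state(small_geometry):
    return build_half_sarcomere(small_geometry, FilamentParams(),
                                LatticeState(face_spacing=15.0))


@pytest.fixture
def default_state():
    return build_half_sarcomere()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def bind_head(state, head, site_flat, strong=False):
    """Manually attach a head to a site (test helper)."""
    state.head_state[head] = 2 if strong else 1
    state.head_site[head] = site_flat
    state.site_occupant[site_flat] = head
    state.balanced = False
    return state
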