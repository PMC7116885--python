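import numpy as np
import pytest

from fibroclefts import (
    FibrosisNetwork,
    make_cross_testcase,
    make_fan_2d,
    make_grid_2d,
    make_slab_3d,
    make_tet_fan_3d,
    probability_map,
    synthetic_lge_fixture,
    tag_lge,
)
from fibroclefts.cells import MitchellSchaeffer, TenTusscher2006Epi, resting_state


@pytest.fixture(scope="session")
def fan5():
    """Closed 5-triangle fan: the 2D local-connectivity worked example."""
    return make_fan_2d(5)


@pytest.fixture(scope="session")
def fan_network():
    """Split edges between elements (e1,e2)... i.e. hub edges to ring 0, 2, 3."""
    return FibrosisNetwork({(0, 5), (2, 5), (3, 5)})


@pytest.fixture(scope="session")
def tet_fan():
    """4-tet fan around an interior edge: the 3D fallback worked example."""
    return make_tet_fan_3d()


@pytest.fixture(scope="session")
def cross_tight():
    return make_cross_testcase("tight")


@pytest.fixture(scope="session")
def cross_leaky():
    return make_cross_testcase("leaky")


@pytest.fixture(scope="session")
def lge_slab():
    """Small tagged slab with a central synthetic enhancement zone."""
    slab = make_slab_3d((4.0, 4.0, 2.0), 1.0)
    intensity = synthetic_lge_fixture(slab, (2.0, 2.0, 1.0), 2.5)
    tag_lge(slab, intensity)
    return slab, intensity


@pytest.fixture(scope="session")
def ms_model():
    return MitchellSchaeffer()


@pytest.fixture(scope="session")
def tt_model():
    return TenTusscher2006Epi()


@pytest.fixture(scope="session")
def tt_rest(tt_model):
    """Relaxed quiescent state of the default ionic model (cached once)."""
    return resting_state(tt_model)
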