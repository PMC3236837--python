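import math

import numpy as np
import pytest

from vesseltort.costs import compute_cost
from vesseltort.phantoms import PhantomSpec, _polyline, make_phantom, rasterize_tube


@pytest.fixture(scope="session")
def straight_tube():
    """Capped cylinder along x: length 60, tube radius 3."""
    line = _polyline([(0.0, 0.0, 0.0), (60.0, 0.0, 0.0)])
    return rasterize_tube([line], tube_radius=3.0)


@pytest.fixture(scope="session")
def comb_phantom():
    """Five-tooth comb, tube radius 3 (the standard validation comb)."""
    spec = PhantomSpec(kind="comb", tube_radius=3.0, spine_length=100.0,
                       tooth_length=40.0, n_teeth=5, tooth_spacing=20.0)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def comb_dfecom_cost(comb_phantom):
    return compute_cost(comb_phantom.mask, "DFE_COM")


@pytest.fixture(scope="session")
def small_helix():
    """One-coil helix, radius 30, tube radius 3, pitch 15(2pi)."""
    spec = PhantomSpec(kind="helix", helix_radius=30.0,
                       pitch=15.0 * 2 * math.pi, turns=1.0, tube_radius=3.0)
    return make_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
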