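import numpy as np
import pytest

from cablenet.membrane import HHRegionParams, MechanismSpec
from cablenet.morphology import make_fixture


@pytest.fixture
def ball_and_stick():
    return make_fixture("ball_and_stick", n_seg=20, length_um=200.0,
                        radius_um=1.0)


@pytest.fixture
def stick_with_axon():
    return make_fixture("ball_and_stick", n_seg=20, length_um=200.0,
                        radius_um=0.7, soma_radius_um=8.0,
                        axon_n_seg=10, axon_length_um=100.0,
                        axon_radius_um=0.4)


@pytest.fixture
def binary_tree():
    return make_fixture("binary_tree", depth=3, segment_length_um=40.0)


@pytest.fixture
def two_cell_net():
    return make_fixture("two_cell", gap_um=2.0)


@pytest.fixture
def passive_spec():
    """Pure-leak membrane with zero reversal (rest at 0 V)."""
    g_l = 5.0
    regions = {r: HHRegionParams(g_K=0.0, g_Na=0.0, g_l=g_l)
               for r in ("axon", "soma", "dendrite")}
    return MechanismSpec(regions=regions, c_T=1.0, V_rest=0.0,
                         E_l={r: 0.0 for r in ("axon", "soma", "dendrite")})


@pytest.fixture
def fluxless_spec():
    """No membrane transport at all (sealed passive cable)."""
    regions = {r: HHRegionParams(g_K=0.0, g_Na=0.0, g_l=0.0)
               for r in ("axon", "soma", "dendrite")}
    return MechanismSpec(regions=regions, c_T=1.0, V_rest=0.0,
                         E_l={r: 0.0 for r in ("axon", "soma", "dendrite")})


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
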