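import numpy as np
import pytest

import mitoswitch as mw
from mitoswitch.core_model import RCState, simulate, reference_initial_state
from mitoswitch.phantom import generate_phantom
from mitoswitch.spatial import SpatialParams, GlutamateSolver, H2O2Solver


@pytest.fixture(scope="session")
def params():
    return mw.ModelParams()


@pytest.fixture(scope="session")
def rest_state(params):
    """Reference ATP-producing state: the shipped initial condition relaxed
    at 0.01 mM external glutamate."""
    tr = simulate(reference_initial_state(params),
                  params.with_updates(glu_o=0.01), (0.0, 600.0), n_out=60)
    return tr.final_state


@pytest.fixture(scope="session")
def ros_state(params):
    """A settled ROS-producing state at 0.01 mM glutamate (second attractor)."""
    seed = RCState(qh2=4.0, nadh=19.0, atp=2.0, dpsi=5.0, oaa=0.002, akg=0.05,
                   succ=1.0, mal=0.05, glu_m=2.0, asp=0.1)
    tr = simulate(seed, params.with_updates(glu_o=0.01), (0.0, 400.0), n_out=50)
    return tr.final_state


@pytest.fixture(scope="session")
def phantom():
    return generate_phantom(seed=0)


@pytest.fixture(scope="session")
def spatial_params():
    return SpatialParams()


@pytest.fixture(scope="session")
def glu_solver(phantom, spatial_params):
    return GlutamateSolver(phantom, spatial_params)


@pytest.fixture(scope="session")
def h2o2_solver(phantom, spatial_params):
    return H2O2Solver(phantom, spatial_params)


@pytest.fixture
def arbitrary_state():
    """A generic interior state used by transcription-oracle tests."""
    return RCState(qh2=1.7, nadh=6.2, atp=11.0, dpsi=150.0, oaa=0.3, akg=0.5,
                   succ=2.2, mal=0.9, glu_m=1.4, asp=0.6, ph=7.3, ca_ext=4.0)
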