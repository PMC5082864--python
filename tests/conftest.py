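import numpy as np
import pytest

from fetocap import TransportParameters, bump_shape
from fetocap.axisym import build_mesh, calibrate_pressure, solve_oxygen, solve_stokes


@pytest.fixture(scope="session")
def params():
    return TransportParameters()


@pytest.fixture(scope="session")
def straight_tube():
    """Straight capillary at the reference configuration (R0 = 4.7 um, L = 76 um)."""
    shape = bump_shape(4.7, 4.7, 31.0, 76.0)
    mesh = build_mesh(shape)
    dP = calibrate_pressure(4.7, 76.0, 1e-3, 300.0)
    flow = solve_stokes(mesh, 1e-3, dP)
    return shape, mesh, dP, flow


@pytest.fixture(scope="session")
def straight_tube_oxygen(straight_tube, params):
    _, mesh, _, flow = straight_tube
    return solve_oxygen(mesh, flow, params)


@pytest.fixture(scope="session")
def dilated_tube(params):
    """Measured dilation geometry: R0 = 4.7, R_max = 6.8, lambda = 31, L = 76."""
    shape = bump_shape(4.7, 6.8, 31.0, 76.0)
    mesh = build_mesh(shape)
    dP = calibrate_pressure(4.7, 76.0, 1e-3, 300.0)
    flow = solve_stokes(mesh, 1e-3, dP)
    sol = solve_oxygen(mesh, flow, params)
    return shape, mesh, dP, flow, sol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
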