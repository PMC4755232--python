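import numpy as np
import pytest

from rigidbd.grids import Grid3D
from rigidbd.model import Conformation, RigidBodyState, SimulationConfig, Solute


@pytest.fixture
def rng():
    return np.random.default_rng(20250920)


@pytest.fixture
def affine_grid():
    """Grid sampled from f(x,y,z) = 2x + 3y - z on [0,2]^3, spacing 0.5."""
    n = 5
    h = 0.5
    ax = h * np.arange(n)
    x, y, z = np.meshgrid(ax, ax, ax, indexing="ij")
    return Grid3D(origin=np.zeros(3), spacing=h, values=2 * x + 3 * y - z)


def make_point_solute(
    d_trans=0.01,
    d_rot=1e-3,
    stokes_radius=2.0,
    charge=None,
    grid_set=None,
    position=(0.0, 0.0, 0.0),
):
    """Single-atom test solute, optionally with one effective charge at its centre."""
    kwargs = dict(
        atom_positions=np.zeros((1, 3)),
        d_trans=d_trans,
        d_rot=d_rot,
        stokes_radius=stokes_radius,
        grid_set=grid_set,
    )
    if charge is not None:
        kwargs["site_positions"] = np.zeros((1, 3))
        kwargs["site_charges"] = [charge]
    sol = Solute(conformations=[Conformation(**kwargs)])
    sol.state = RigidBodyState(np.asarray(position, dtype=float))
    return sol


@pytest.fixture
def point_solute_factory():
    return make_point_solute


class ZeroRNG:
    """Degenerate generator: every draw is zero (drift-only propagation)."""

    def normal(self, loc=0.0, scale=1.0, size=None):
        return np.zeros(size) if size is not None else 0.0

    def random(self, size=None):
        return np.zeros(size) if size is not None else 0.0


@pytest.fixture
def zero_rng():
    return ZeroRNG()


@pytest.fixture
def default_config():
    return SimulationConfig(dt=1.0, temperature=298.15)
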