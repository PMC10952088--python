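import numpy as np
import pytest

from waterkit import Trajectory, assign_water_topology
from waterkit.synthetic import (
    brownian_com_trajectory,
    grid_topology,
    ideal_gas_trajectory,
    make_tetrahedral_ice,
    rotor_trajectory,
)


@pytest.fixture(scope="session")
def ice():
    """64-molecule proton-ordered cubic ice (2×2×2 cells, a_OO = 2.75 Å)."""
    frame, topo = make_tetrahedral_ice(n_cells=2, a_OO=2.75, seed=11)
    return frame, topo


@pytest.fixture(scope="session")
def ice_traj(ice):
    frame, topo = ice
    traj = Trajectory(frame.positions[None], frame.elements, frame.box_edge)
    return traj, topo


@pytest.fixture(scope="session")
def brownian():
    """64 Brownian walkers, D = 0.23 Å²/ps, 2000 frames at 0.01 ps."""
    traj = brownian_com_trajectory(
        n_mol=64, L=12.445, D_true=0.23, dt=0.01, n_frames=2000, seed=101
    )
    return traj, grid_topology(64), 0.23


@pytest.fixture(scope="session")
def rotor():
    """64 isotropic rotors, D_r = 0.05 ps⁻¹, 2000 frames at 0.02 ps (40 ps ≈ 12 τ₂)."""
    traj = rotor_trajectory(n_mol=64, D_r=0.05, dt=0.02, n_frames=2000, seed=7)
    return traj, grid_topology(64), 0.05


@pytest.fixture(scope="session")
def gas():
    """Ideal-gas null model at roughly liquid-water density (64 in 12.445 Å)."""
    traj = ideal_gas_trajectory(n_mol=64, L=12.445, n_frames=200, seed=3)
    return traj, grid_topology(64)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
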