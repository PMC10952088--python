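"""Synthetic trajectories and configurations with known ground truth.

Every analysis stage in the package has a generator here whose statistical
structure is known in closed form: Brownian centre-of-mass walks for the
Einstein diffusion estimator, isotropic rigid-rotor diffusion for the
orientational relaxation times, proton-ordered cubic ice obeying the
Bernal–Fowler rules for H-bond counting and coordination numbers, ideal-gas
configurations as the flat-RDF null model, two-molecule H-bond geometries
with controllable donor tilt, and analytic energy-vs-volume backends for the
equilibrium-density scan.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .trajectory import Frame, Trajectory, WaterTopology, minimum_image
from .units import MASS_H, MASS_O

__all__ = [
    "RigidWaterTemplate",
    "EnergyBackend",
    "brownian_com_trajectory",
    "rotor_trajectory",
    "make_tetrahedral_ice",
    "ideal_gas_trajectory",
    "dimer_frame",
    "quadratic_EV_backend",
]

#: (frame, volume in Å³) → scalar energy, arbitrary units. Must be
#: deterministic and finite over the scanned volume range.
EnergyBackend = Callable[[Frame, float], float]


@dataclass(frozen=True)
class RigidWaterTemplate:
    """Rigid water monomer geometry (bond length Å, angle degrees)."""

    oh_length: float = 0.97
    hoh_angle: float = 104.5

    def sites(self) -> np.ndarray:
        """O, H1, H2 coordinates relative to the molecular COM, bisector +x.

        COM-centring makes the generators' nominal molecule positions equal
        to the mass-weighted centres the analysis code computes.
        """
        half = np.deg2rad(self.hoh_angle) / 2.0
        h1 = self.oh_length * np.array([np.cos(half), np.sin(half), 0.0])
        h2 = self.oh_length * np.array([np.cos(half), -np.sin(half), 0.0])
        raw = np.array([np.zeros(3), h1, h2])
        m = np.array([MASS_O, MASS_H, MASS_H])
        return raw - (m[:, None] * raw).sum(axis=0) / m.sum()


def _assemble(coms: np.ndarray, orientations: np.ndarray, template: RigidWaterTemplate) -> np.ndarray:
    """Place rigid monomers: per-molecule rotation matrices applied to template sites."""
    sites = template.sites()  # (3, 3)
    # orientations: (n_mol, 3, 3) rotation matrices
    rotated = np.einsum("mij,sj->msi", orientations, sites)
    return (coms[:, None, :] + rotated).reshape(-1, 3)


def _elements(n_mol: int) -> list[str]:
    return ["O", "H", "H"] * n_mol

def _grid_coms(n_mol: int, L: float) -> np.ndarray:
    """Non-overlapping cubic grid of molecular centres inside an L box."""
    k = int(np.ceil(n_mol ** (1.0 / 3.0)))
    pts = (np.arange(k) + 0.5) * (L / k)
    grid = np.stack(np.meshgrid(pts, pts, pts, indexing="ij"), -1).reshape(-1, 3)
    return grid[:n_mol]


def grid_topology(n_mol: int) -> WaterTopology:
    """Topology for trajectories assembled molecule-by-molecule (O, H, H order)."""
    return WaterTopology([(3 * i, 3 * i + 1, 3 * i + 2) for i in range(n_mol)])


def brownian_com_trajectory(
    n_mol: int,
    L: float,
    D_true: float,
    dt: float,
    n_frames: int,
    seed: int,
    template: RigidWaterTemplate | None = None,
) -> Trajectory:
    """Rigid monomers whose COMs perform independent Gaussian walks.

    Per-axis step variance is 2·D_true·dt, so the ensemble MSD grows as
    6·D_true·t. Positions are wrapped into the box; the unwrapped COM record
    is kept in ``metadata['unwrapped_com']`` for cross-checking the unwrap
    pass. Orientations are fixed. Molecular overlap is not checked.
    """
    if D_true < 0:
        raise ValueError("D_true must be non-negative")
    if dt <= 0:
        raise ValueError("dt must be positive")
    template = template or RigidWaterTemplate()
    rng = np.random.default_rng(seed)
    coms0 = _grid_coms(n_mol, L)
    steps = rng.normal(0.0, np.sqrt(2.0 * D_true * dt), size=(n_frames - 1, n_mol, 3))
    unwrapped = np.concatenate([coms0[None], coms0[None] + np.cumsum(steps, axis=0)])
    orientations = np.broadcast_to(np.eye(3), (n_mol, 3, 3))
    positions = np.empty((n_frames, 3 * n_mol, 3))
    for t in range(n_frames):
        coms_wrapped = unwrapped[t] % L
        positions[t] = _assemble(coms_wrapped, orientations, template)
    return Trajectory(
        positions,
        _elements(n_mol),
        L,
        frame_spacing=dt,
        metadata={
            "generator": "brownian_com",
            "D_true": D_true,
            "seed": seed,
            "unwrapped_com": unwrapped,
        },
    )


def rotor_trajectory(
    n_mol: int,
    D_r: float,
    dt: float,
    n_frames: int,
    seed: int,
    L: float | None = None,
    template: RigidWaterTemplate | None = None,
) -> Trajectory:
    """Rigid monomers undergoing isotropic rotational diffusion, COMs fixed.

    Each step composes an exponential-map rotation drawn from a Gaussian
    axis-angle increment with per-axis variance 2·D_r·dt; in the small-dt
    limit the orientational ACFs decay as C_n(t) = exp(−n(n+1)·D_r·t).
    """
    if D_r < 0:
        raise ValueError("D_r must be non-negative")
    template = template or RigidWaterTemplate()
    rng = np.random.default_rng(seed)
    if L is None:
        # comfortably separated grid: 4 Å spacing
        L = 4.0 * int(np.ceil(n_mol ** (1.0 / 3.0)))
    coms = _grid_coms(n_mol, L)
    # random initial orientations so the ensemble is isotropic from t=0
    mats = Rotation.random(n_mol, random_state=rng).as_matrix()
    positions = np.empty((n_frames, 3 * n_mol, 3))
    positions[0] = _assemble(coms, mats, template)
    sigma = np.sqrt(2.0 * D_r * dt)
    for t in range(1, n_frames):
        rotvecs = rng.normal(0.0, sigma, size=(n_mol, 3))
        mats = Rotation.from_rotvec(rotvecs).as_matrix() @ mats
        positions[t] = _assemble(coms, mats, template)
    return Trajectory(
        positions,
        _elements(n_mol),
        L,
        frame_spacing=dt,
        metadata={"generator": "rotor", "D_r": D_r, "seed": seed},
    )


# ---------------------------------------------------------------------------
# Proton-ordered cubic ice
# ---------------------------------------------------------------------------

def _diamond_lattice(n_cells: int, a: float) -> np.ndarray:
    """Fractional diamond (cubic-ice oxygen) sublattice positions, Å."""
    basis = np.array(
        [
            [0.00, 0.00, 0.00],
            [0.00, 0.50, 0.50],
            [0.50, 0.00, 0.50],
            [0.50, 0.50, 0.00],
            [0.25, 0.25, 0.25],
            [0.25, 0.75, 0.75],
            [0.75, 0.25, 0.75],
            [0.75, 0.75, 0.25],
        ]
    )
    cells = np.stack(
        np.meshgrid(*(np.arange(n_cells),) * 3, indexing="ij"), -1
    ).reshape(-1, 3)
    frac = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) / n_cells
    return frac * (n_cells * a)


def make_tetrahedral_ice(
    n_cells: int,
    a_OO: float = 2.75,
    seed: int = 0,
    oh_length: float = 0.97,
) -> tuple[Frame, WaterTopology]:
    """Proton-ordered cubic ice obeying the Bernal–Fowler ice rules.

    Oxygens sit on a diamond sublattice with nearest-neighbour separation
    ``a_OO`` under periodic boundaries; every O–O link carries exactly one H,
    placed on the axis at ``oh_length`` from its donor oxygen, and every
    oxygen donates exactly two. The two-in/two-out proton assignment is an
    Eulerian-circuit orientation of the 4-regular bond graph, which satisfies
    the ice rules by construction; ``seed`` shuffles the traversal.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    a = 4.0 * a_OO / np.sqrt(3.0)
    L = n_cells * a
    o_pos = _diamond_lattice(n_cells, a)
    n_o = len(o_pos)

    # nearest-neighbour O-O bonds at distance a_OO (minimum image)
    d = minimum_image(o_pos[:, None, :] - o_pos[None, :, :], L)
    dist = np.linalg.norm(d, axis=2)
    cut = 1.1 * a_OO
    g = nx.MultiGraph()
    g.add_nodes_from(range(n_o))
    ii, jj = np.nonzero((dist < cut) & (dist > 1e-9))
    for i, j in zip(ii, jj):
        if i < j:
            g.add_edge(int(i), int(j))
    degrees = dict(g.degree())
    if any(v != 4 for v in degrees.values()):
        raise ValueError("oxygen lattice is not 4-coordinated; check a_OO")

    rng = np.random.default_rng(seed)
    # Randomise the adjacency traversal (edge insertion order and circuit
    # start), then orient edges along an Eulerian circuit: every vertex ends
    # with in-degree = out-degree = 2.
    edges = list(g.edges())
    rng.shuffle(edges)
    g = nx.MultiGraph()
    g.add_nodes_from(range(n_o))
    g.add_edges_from(edges)
    source = int(rng.integers(n_o))
    h_pos = []
    molecules_h: dict[int, list[int]] = {i: [] for i in range(n_o)}
    for u, v in nx.eulerian_circuit(g, source=source):
        # H belongs to u (the edge is traversed u -> v)
        axis = minimum_image(o_pos[v] - o_pos[u], L)
        axis /= np.linalg.norm(axis)
        h_pos.append(o_pos[u] + oh_length * axis)
        molecules_h[u].append(n_o + len(h_pos) - 1)

    positions = np.vstack([o_pos, np.array(h_pos)]) % L
    elements = ["O"] * n_o + ["H"] * len(h_pos)
    molecules = [(i, molecules_h[i][0], molecules_h[i][1]) for i in range(n_o)]
    frame = Frame(positions, elements, L)
    topo = WaterTopology(molecules)
    return frame, topo


def ideal_gas_trajectory(
    n_mol: int,
    L: float,
    n_frames: int,
    seed: int,
    template: RigidWaterTemplate | None = None,
) -> Trajectory:
    """Uniform, frame-independent molecular placements with random orientations.

    The null model for RDF normalisation: g(r) = 1 for every pair species.
    """
    if n_mol < 2:
        raise ValueError("n_mol must be >= 2")
    template = template or RigidWaterTemplate()
    rng = np.random.default_rng(seed)
    positions = np.empty((n_frames, 3 * n_mol, 3))
    for t in range(n_frames):
        coms = rng.uniform(0.0, L, size=(n_mol, 3))
        mats = Rotation.random(n_mol, random_state=rng).as_matrix()
        positions[t] = _assemble(coms, mats, template) % L
    return Trajectory(
        positions,
        _elements(n_mol),
        L,
        frame_spacing=1.0,
        metadata={"generator": "ideal_gas", "seed": seed},
    )


def dimer_frame(
    d_OO: float,
    tilt_deg: float = 0.0,
    L: float = 20.0,
    template: RigidWaterTemplate | None = None,
) -> tuple[Frame, WaterTopology]:
    """Two waters in a donor–acceptor geometry with controllable donor tilt.

    The donor O sits at the box centre with one O–H bond making ``tilt_deg``
    with the O–O axis (+x); the acceptor is oriented to accept, with both of
    its hydrogens pointing away from the donor.
    """
    if d_OO <= 0:
        raise ValueError("d_OO must be positive")
    if not (0 <= tilt_deg < 90):
        raise ValueError("tilt_deg must be in [0, 90)")
    template = template or RigidWaterTemplate()
    t = np.deg2rad(tilt_deg)
    c = L / 2.0
    od = np.array([c, c, c])
    oa = od + np.array([d_OO, 0.0, 0.0])
    # donor: bonded H tilted off the O-O axis in the xy plane
    h1 = od + template.oh_length * np.array([np.cos(t), np.sin(t), 0.0])
    # second donor H at the template angle from the first, rotated away
    ang = np.deg2rad(template.hoh_angle)
    h2 = od + template.oh_length * np.array(
        [np.cos(t + ang), np.sin(t + ang), 0.0]
    )
    # acceptor: bisector pointing +x (away from donor), H's on the far side
    half = np.deg2rad(template.hoh_angle) / 2.0
    ha1 = oa + template.oh_length * np.array([np.cos(half), np.sin(half), 0.0])
    ha2 = oa + template.oh_length * np.array([np.cos(half), -np.sin(half), 0.0])
    positions = np.array([od, h1, h2, oa, ha1, ha2])
    frame = Frame(positions, ["O", "H", "H", "O", "H", "H"], L)
    topo = WaterTopology([(0, 1, 2), (3, 4, 5)])
    return frame, topo


def quadratic_EV_backend(V0: float, curvature: float = 1.0) -> EnergyBackend:
    """Analytic energy backend E(V) = curvature·(V − V0)², coordinate-independent."""
    if V0 <= 0:
        raise ValueError("V0 must be positive")
    if curvature <= 0:
        raise ValueError("curvature must be positive")

    def backend(frame: Frame, volume: float) -> float:
        return curvature * (volume - V0) ** 2

    return backend
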