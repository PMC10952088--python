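"""Smoothed two-function hydrogen-bond criterion and angular distributions.

A donor H belonging to molecule i is counted as H-bonded to an acceptor
oxygen O_j when the product of two smoothed rectangle functions exceeds a
threshold (default 0.5):

* the first acts on the donor–acceptor O–O distance, centred on the first
  coordination shell (d0 = 2.8 Å, Δ = 0.45 Å, exponents 10/16);
* the second acts on the path-length excess
  d' = |O_iH| + |HO_j| − |O_iO_j|, which is zero for a collinear bond and
  grows as the donor-hydrogen direction tilts (d0 = 0, Δ = 0.4 Å,
  exponents 4/8).

Each switch is the rational form f(x) = (1 − x²ⁿ)/(1 − x²ᵐ) with
x = (d − d0)/Δ and n < m: ≈1 inside the window, smoothly decaying to 0
outside, with the removable singularity at |x| = 1 evaluating to n/m. The
doubled exponents make the window symmetric about d0 and steep enough that
the d′ function (n=4, m=8, Δ=0.4 Å) drops below 0.05 once the path excess
passes ~0.55 Å, while its window-edge value n/m = 0.5 coincides with the
counting threshold.

Angular distributions restrict to first-shell geometries (O–O < 3.4 Å,
H···O < 2.5 Å) and histogram β, the angle at the donor oxygen between the
O→H and O→O_acceptor directions; the hydrogen-centred complementary angle
α = 180° − ∠(O–H···O) is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .trajectory import Frame, Trajectory, WaterTopology, minimum_image

__all__ = [
    "SwitchParams",
    "HBondCriterion",
    "HBondStats",
    "AngleDistribution",
    "rect_switch",
    "excess_path_length",
    "is_hbonded",
    "hbond_stats",
    "angle_distribution",
]


@dataclass(frozen=True)
class SwitchParams:
    """Parameters of one smoothed rectangle function."""

    d0: float  # centre, Å
    delta: float  # half-width, Å
    n: int = 10
    m: int = 16

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.n <= 0 or int(self.n) != self.n or int(self.m) != self.m:
            raise ValueError("n and m must be positive integers")
        if self.n >= self.m:
            raise ValueError("require n < m")


@dataclass(frozen=True)
class HBondCriterion:
    """Product-of-switches H-bond detector with the standard water defaults."""

    distance: SwitchParams = field(
        default_factory=lambda: SwitchParams(d0=2.8, delta=0.45, n=10, m=16)
    )
    path_excess: SwitchParams = field(
        default_factory=lambda: SwitchParams(d0=0.0, delta=0.4, n=4, m=8)
    )
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")

    @property
    def oo_cutoff(self) -> float:
        """O–O distance beyond which the first factor is certainly < threshold.

        At x = 2 the switch is already ≤ (2ⁿ−1)/(2ᵐ−1) ≪ threshold, so
        d0 + 2Δ is a safe neighbour-search cutoff.
        """
        return self.distance.d0 + 2.0 * self.distance.delta


def rect_switch(d, params: SwitchParams):
    """Smoothed rectangle f(d) = (1 − x²ⁿ)/(1 − x²ᵐ), x = (d − d0)/Δ.

    Total function: at |x| = 1 the removable singularity evaluates to n/m;
    the doubled even exponents make the window symmetric about d0. Accepts
    scalars or arrays.
    """
    x = (np.asarray(d, dtype=float) - params.d0) / params.delta
    xn = x ** (2 * params.n)
    xm = x ** (2 * params.m)
    denom = 1.0 - xm
    limit = params.n / params.m
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(np.abs(denom) < 1e-12, limit, (1.0 - xn) / denom)
    return float(out) if np.isscalar(d) else out


def excess_path_length(donor_O, H, acceptor_O, box_edge: float) -> float:
    """Triangle-inequality slack |O_dH| + |HO_a| − |O_dO_a| (minimum image), Å."""
    donor_O = np.asarray(donor_O, dtype=float)
    H = np.asarray(H, dtype=float)
    acceptor_O = np.asarray(acceptor_O, dtype=float)
    d_oh = np.linalg.norm(minimum_image(H - donor_O, box_edge))
    d_ha = np.linalg.norm(minimum_image(acceptor_O - H, box_edge))
    d_oo = np.linalg.norm(minimum_image(acceptor_O - donor_O, box_edge))
    return float(d_oh + d_ha - d_oo)


def is_hbonded(
    donor_mol: tuple[int, int, int],
    h_index: int,
    acceptor_mol: tuple[int, int, int],
    frame: Frame,
    criterion: HBondCriterion | None = None,
) -> tuple[bool, float]:
    """Evaluate the product criterion for one (donor H, acceptor O) pair.

    Returns ``(bonded, product)``. ``h_index`` must be one of the donor
    molecule's hydrogens.
    """
    criterion = criterion or HBondCriterion()
    if h_index not in donor_mol[1:]:
        raise ValueError(
            f"H atom {h_index} does not covalently belong to donor molecule {donor_mol}"
        )
    od = frame.positions[donor_mol[0]]
    oa = frame.positions[acceptor_mol[0]]
    h = frame.positions[h_index]
    d_oo = float(np.linalg.norm(minimum_image(oa - od, frame.box_edge)))
    d_prime = excess_path_length(od, h, oa, frame.box_edge)
    product = rect_switch(d_oo, criterion.distance) * rect_switch(
        d_prime, criterion.path_excess
    )
    return bool(product > criterion.threshold), float(product)


@dataclass
class HBondStats:
    """Per-frame, per-molecule H-bond participation counts."""

    counts: np.ndarray  # (n_frames, n_mol) — bonds each molecule participates in
    donated: np.ndarray  # (n_frames, n_mol)
    accepted: np.ndarray  # (n_frames, n_mol)
    n_bonds: np.ndarray  # (n_frames,) distinct bonds per frame

    @property
    def h_per_molecule(self) -> float:
        """Trajectory-average H-bonds per molecule (each bond credited twice)."""
        return float(np.mean(self.counts))

    def to_dataframe(self) -> pd.DataFrame:
        nf, nm = self.counts.shape
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(nf), nm),
                "molecule": np.tile(np.arange(nm), nf),
                "count": self.counts.ravel(),
                "donated": self.donated.ravel(),
                "accepted": self.accepted.ravel(),
            }
        )


def _frame_bonds_bruteforce(pos, topology, L, criterion):
    """All (donor mol, H atom, acceptor mol) bonds by explicit double loop."""
    bonds = []
    mols = topology.molecules
    for i, (oi, h1, h2) in enumerate(mols):
        for j, (oj, _, _) in enumerate(mols):
            if i == j:
                continue
            d_oo = np.linalg.norm(minimum_image(pos[oj] - pos[oi], L))
            f1 = rect_switch(d_oo, criterion.distance)
            for h in (h1, h2):
                dprime = excess_path_length(pos[oi], pos[h], pos[oj], L)
                if f1 * rect_switch(dprime, criterion.path_excess) > criterion.threshold:
                    bonds.append((i, h, j))
    return bonds


def _frame_bonds_neighborlist(pos, topology, L, criterion):
    """Same bonds via a periodic KD-tree neighbour search within the O–O cutoff."""
    o_idx = topology.oxygen_indices
    o_pos = np.mod(pos[o_idx], L)
    tree = cKDTree(o_pos, boxsize=L)
    pairs = tree.query_pairs(criterion.oo_cutoff, output_type="ndarray")
    bonds = []
    mols = topology.molecules
    for i, j in pairs:
        d_oo = np.linalg.norm(minimum_image(pos[o_idx[j]] - pos[o_idx[i]], L))
        f1 = rect_switch(d_oo, criterion.distance)
        if f1 <= criterion.threshold:
            continue
        for donor, acceptor in ((i, j), (j, i)):
            oi = mols[donor][0]
            oj = mols[acceptor][0]
            for h in mols[donor][1:]:
                dprime = excess_path_length(pos[oi], pos[h], pos[oj], L)
                if f1 * rect_switch(dprime, criterion.path_excess) > criterion.threshold:
                    bonds.append((donor, h, acceptor))
    return bonds


def hbond_stats(
    traj: Trajectory,
    topology: WaterTopology,
    criterion: HBondCriterion | None = None,
    method: str = "neighborlist",
) -> HBondStats:
    """Count H-bonds over a trajectory.

    Each bond is one (donor H, acceptor O) realisation passing the product
    criterion; it is credited to both partner molecules, so a perfect
    tetrahedral network gives 4 bonds per molecule. ``method`` selects the
    periodic KD-tree neighbour search (default) or the O(N²) double loop
    (``"bruteforce"``), kept as an independent cross-check.
    """
    criterion = criterion or HBondCriterion()
    finder = {
        "neighborlist": _frame_bonds_neighborlist,
        "bruteforce": _frame_bonds_bruteforce,
    }[method]
    nf, nm = traj.n_frames, topology.n_molecules
    counts = np.zeros((nf, nm), dtype=int)
    donated = np.zeros((nf, nm), dtype=int)
    accepted = np.zeros((nf, nm), dtype=int)
    n_bonds = np.zeros(nf, dtype=int)
    for t in range(nf):
        bonds = finder(traj.positions[t], topology, traj.box_edge, criterion)
        n_bonds[t] = len(bonds)
        for donor, _, acceptor in bonds:
            donated[t, donor] += 1
            accepted[t, acceptor] += 1
    counts = donated + accepted
    return HBondStats(counts, donated, accepted, n_bonds)


@dataclass
class AngleDistribution:
    """Normalised H-bond angle histograms (degrees)."""

    beta_grid: np.ndarray  # bin centres
    beta_density: np.ndarray  # P(β), ∫P dβ = 1
    alpha_grid: np.ndarray
    alpha_density: np.ndarray
    cutoff_OO: float
    cutoff_HO: float
    n_samples: int

    def write(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.beta_grid, self.beta_density]),
            fmt="%.6f",
            header="beta(deg)  P(beta)",
        )


def angle_distribution(
    traj: Trajectory,
    topology: WaterTopology,
    cutoff_OO: float = 3.4,
    cutoff_HO: float = 2.5,
    bin_width_deg: float = 1.0,
    max_angle_deg: float = 90.0,
) -> AngleDistribution:
    """Histogram H-bond angles over first-shell donor–acceptor geometries.

    β is measured at the donor oxygen between O_d→H and O_d→O_a; pairs
    qualify when the donor–acceptor distance is below ``cutoff_OO`` and the
    hydrogen–acceptor distance below ``cutoff_HO``. The hydrogen-centred
    complement α = 180° − ∠(O_d–H–O_a) is histogrammed on the same grid.
    Densities integrate to 1 over degrees.
    """
    L = traj.box_edge
    o_idx = topology.oxygen_indices
    betas: list[np.ndarray] = []
    alphas: list[np.ndarray] = []
    for t in range(traj.n_frames):
        pos = traj.positions[t]
        o_pos = np.mod(pos[o_idx], L)
        tree = cKDTree(o_pos, boxsize=L)
        pairs = tree.query_pairs(cutoff_OO, output_type="ndarray")
        for i, j in pairs:
            for donor, acceptor in ((i, j), (j, i)):
                od = pos[topology.molecules[donor][0]]
                oa = pos[topology.molecules[acceptor][0]]
                v_oo = minimum_image(oa - od, L)
                d_oo = np.linalg.norm(v_oo)
                for h in topology.molecules[donor][1:]:
                    v_oh = minimum_image(pos[h] - od, L)
                    v_ha = minimum_image(oa - pos[h], L)
                    if np.linalg.norm(v_ha) >= cutoff_HO:
                        continue
                    cosb = np.dot(v_oh, v_oo) / (np.linalg.norm(v_oh) * d_oo)
                    betas.append(np.degrees(np.arccos(np.clip(cosb, -1, 1))))
                    cos_oha = np.dot(-v_oh, v_ha) / (
                        np.linalg.norm(v_oh) * np.linalg.norm(v_ha)
                    )
                    oha = np.degrees(np.arccos(np.clip(cos_oha, -1, 1)))
                    alphas.append(180.0 - oha)
    if not betas:
        import warnings

        warnings.warn("no qualifying H-bond geometries; empty distribution")
    edges = np.arange(0.0, max_angle_deg + bin_width_deg, bin_width_deg)
    centres = 0.5 * (edges[:-1] + edges[1:])

    def _density(vals):
        hist = np.histogram(np.asarray(vals, dtype=float), bins=edges)[0].astype(float)
        total = hist.sum() * bin_width_deg
        return hist / total if total > 0 else hist

    return AngleDistribution(
        centres,
        _density(betas),
        centres,
        _density(alphas),
        cutoff_OO,
        cutoff_HO,
        len(betas),
    )
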