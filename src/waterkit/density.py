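"""Equilibrium density from energy-vs-volume scans around trajectory snapshots.

For each snapshot the molecular centres of mass are rescaled homogeneously
with the box (intramolecular geometry held rigid), a pluggable backend
evaluates the total energy at each scaled volume, and the equilibrium volume
is the minimum of an interpolant through the scan points. The density follows
from the snapshot-average equilibrium volume,
ρ = N·M_w / (N_A·V̄_eq).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.optimize import minimize_scalar

from .synthetic import EnergyBackend
from .trajectory import Frame, Trajectory, WaterTopology, minimum_image
from .units import AVOGADRO, MOLAR_MASS_H2O

__all__ = [
    "VolumeScanResult",
    "rescale_com_positions",
    "volume_scan",
    "equilibrium_density",
    "box_density",
]


def box_density(n_mol: int, box_edge: float, molar_mass: float = MOLAR_MASS_H2O) -> float:
    """Mass density (g/cm³) of n_mol molecules in a cubic box of edge L (Å)."""
    if n_mol <= 0 or box_edge <= 0 or molar_mass <= 0:
        raise ValueError("all arguments must be positive")
    volume_cm3 = (box_edge * 1e-8) ** 3
    return n_mol * molar_mass / (AVOGADRO * volume_cm3)


def rescale_com_positions(
    frame: Frame, topology: WaterTopology, scale: float
) -> Frame:
    """Homogeneously rescale molecular COMs with the box, keeping monomers rigid.

    The new box edge is ``scale·L``; every molecule is translated as a rigid
    body so its centre of mass maps to ``scale·COM``. Intramolecular
    geometry is bit-identical (pure translation per molecule).
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    L = frame.box_edge
    coms = topology.com(frame.positions, L)
    new_pos = frame.positions.copy()
    for mol, com in zip(topology.molecules, coms):
        shift = (scale - 1.0) * com
        for idx in mol:
            # keep each site in its molecule-local image before shifting
            local = com + minimum_image(frame.positions[idx] - com, L)
            new_pos[idx] = local + shift
    return Frame(new_pos, list(frame.elements), scale * L, time=frame.time)


@dataclass
class SnapshotScan:
    """One snapshot's energy-vs-volume scan."""

    scales: np.ndarray
    volumes: np.ndarray  # Å³
    energies: np.ndarray  # backend units
    V_eq: float  # Å³, interpolated minimum
    bracketed: bool


@dataclass
class VolumeScanResult:
    """Aggregated equilibrium-volume scan over snapshots."""

    snapshots: list[SnapshotScan]
    n_molecules: int
    molar_mass: float

    @property
    def mean_V_eq(self) -> float:
        return float(np.mean([s.V_eq for s in self.snapshots]))

    @property
    def density(self) -> float:
        """g/cm³ from the snapshot-average equilibrium volume."""
        L_eff = self.mean_V_eq ** (1.0 / 3.0)
        return box_density(self.n_molecules, L_eff, self.molar_mass)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for si, s in enumerate(self.snapshots):
            for sc, v, e in zip(s.scales, s.volumes, s.energies):
                rows.append({"snapshot": si, "scale": sc, "volume": v, "energy": e})
        return pd.DataFrame(rows)


def _interpolated_minimum(volumes: np.ndarray, energies: np.ndarray) -> tuple[float, bool]:
    """Minimum of the E(V) interpolant: cubic spline, quadratic for 3 points."""
    imin = int(np.argmin(energies))
    bracketed = 0 < imin < len(energies) - 1
    if not bracketed:
        warnings.warn("minimum not bracketed by the volume scan")
        return float(volumes[imin]), False
    if len(volumes) == 3:
        coeffs = np.polyfit(volumes, energies, 2)
        return float(-coeffs[1] / (2.0 * coeffs[0])), True
    spline = CubicSpline(volumes, energies)
    res = minimize_scalar(
        spline, bounds=(volumes[imin - 1], volumes[imin + 1]), method="bounded",
        options={"xatol": 1e-12 * volumes[imin]},
    )
    return float(res.x), True


def volume_scan(
    frame: Frame,
    topology: WaterTopology,
    backend: EnergyBackend,
    scales: np.ndarray | None = None,
) -> SnapshotScan:
    """Scan energies over volume scale factors for one snapshot.

    Default scan: 7 linear-scale factors spanning ±6% in volume (±2% in the
    box edge). Volume scale is ``scale³`` relative to the snapshot volume.
    """
    if scales is None:
        scales = (1.0 + np.linspace(-0.06, 0.06, 7)) ** (1.0 / 3.0)
    scales = np.asarray(scales, dtype=float)
    if len(scales) < 3:
        raise ValueError("need at least 3 scan points")
    scales = np.sort(scales)
    volumes = (scales * frame.box_edge) ** 3
    energies = np.array(
        [
            backend(rescale_com_positions(frame, topology, s), v)
            for s, v in zip(scales, volumes)
        ]
    )
    V_eq, bracketed = _interpolated_minimum(volumes, energies)
    return SnapshotScan(scales, volumes, energies, V_eq, bracketed)


def equilibrium_density(
    traj: Trajectory,
    topology: WaterTopology,
    backend: EnergyBackend,
    n_snapshots: int = 30,
    snapshot_spacing: float = 0.2,
    scales: np.ndarray | None = None,
    molar_mass: float = MOLAR_MASS_H2O,
) -> VolumeScanResult:
    """Average equilibrium density over evenly spaced trajectory snapshots.

    ``snapshot_spacing`` is in ps (default 0.2 ps, 30 snapshots). Raises if
    the trajectory is shorter than the requested sampling span.
    """
    if traj.frame_spacing is None:
        raise ValueError("frame_spacing required to space snapshots in ps")
    stride = max(1, int(round(snapshot_spacing / traj.frame_spacing)))
    needed = (n_snapshots - 1) * stride + 1
    if traj.n_frames < needed:
        raise ValueError(
            f"trajectory has {traj.n_frames} frames; "
            f"{needed} needed for {n_snapshots} snapshots every {snapshot_spacing} ps"
        )
    snaps = [
        volume_scan(traj.frame(i * stride), topology, backend, scales)
        for i in range(n_snapshots)
    ]
    return VolumeScanResult(snaps, topology.n_molecules, molar_mass)
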