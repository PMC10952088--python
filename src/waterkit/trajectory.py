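"""Trajectory containers, file I/O, periodic-boundary geometry and water topology.

Frames live in cubic periodic boxes. Internally everything is Å and ps;
readers convert on ingest (Bohr → Å for the CPMD dialect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .units import BOHR_TO_ANGSTROM, MASS_D, MASS_H, MASS_O

__all__ = [
    "Frame",
    "Trajectory",
    "WaterTopology",
    "TrajectoryParseError",
    "TopologyError",
    "minimum_image",
    "assign_water_topology",
    "read_xyz_trajectory",
    "read_cpmd_trajectory",
    "write_xyz_trajectory",
]


class TrajectoryParseError(ValueError):
    """Malformed trajectory file."""


class TopologyError(ValueError):
    """Covalent water-topology assignment failed."""


def minimum_image(vec: np.ndarray, box_edge: float) -> np.ndarray:
    """Map displacement components into (−L/2, L/2].

    The tie at exactly L/2 resolves to +L/2 (deterministic convention).
    """
    if box_edge <= 0:
        raise ValueError("box_edge must be positive")
    v = np.asarray(vec, dtype=float)
    return v - box_edge * np.ceil(v / box_edge - 0.5)


@dataclass
class Frame:
    """One snapshot: per-atom positions (Å), element symbols, cubic box edge (Å)."""

    positions: np.ndarray
    elements: list[str]
    box_edge: float
    time: float | None = None  # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be (n_atoms, 3)")
        if len(self.elements) != len(self.positions):
            raise ValueError("elements length must match positions")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)


@dataclass
class Trajectory:
    """Time-ordered frames sharing atom count, element order and box edge.

    ``positions`` is the (n_frames, n_atoms, 3) stack in Å; ``frame_spacing``
    is the time between consecutive saved frames in ps.
    """

    positions: np.ndarray
    elements: list[str]
    box_edge: float
    frame_spacing: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must be (n_frames, n_atoms, 3)")
        if self.positions.shape[1] != len(self.elements):
            raise ValueError("elements length must match atom count")
        if self.box_edge <= 0:
            raise ValueError("box_edge must be positive")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    @property
    def times(self) -> np.ndarray | None:
        if self.frame_spacing is None:
            return None
        return np.arange(self.n_frames) * self.frame_spacing

    def frame(self, i: int) -> Frame:
        t = None if self.frame_spacing is None else i * self.frame_spacing
        return Frame(self.positions[i], self.elements, self.box_edge, time=t)

    def __len__(self) -> int:
        return self.n_frames


@dataclass
class WaterTopology:
    """Per-molecule (O index, H index, H index) triples.

    ``hydrogen_mass`` selects the COM convention (H vs D); geometry analysis
    is identical for deuterated water.
    """

    molecules: list[tuple[int, int, int]]
    hydrogen_mass: float = MASS_H
    oxygen_mass: float = MASS_O

    @property
    def n_molecules(self) -> int:
        return len(self.molecules)

    @property
    def oxygen_indices(self) -> np.ndarray:
        return np.array([m[0] for m in self.molecules], dtype=int)

    @property
    def hydrogen_indices(self) -> np.ndarray:
        return np.array([[m[1], m[2]] for m in self.molecules], dtype=int)

    def masses(self) -> np.ndarray:
        """Per-site masses in molecule order (O, H, H)."""
        return np.array([self.oxygen_mass, self.hydrogen_mass, self.hydrogen_mass])

    def com(self, positions: np.ndarray, box_edge: float) -> np.ndarray:
        """Molecular centres of mass, with H sites unwrapped to their O first.

        Wrapped coordinates can split a molecule across the box; each H is
        moved to the minimum image relative to its O before mass-weighting.
        """
        pos = np.asarray(positions, dtype=float)
        o = pos[self.oxygen_indices]
        h = pos[self.hydrogen_indices]  # (n_mol, 2, 3)
        h_local = o[:, None, :] + minimum_image(h - o[:, None, :], box_edge)
        m = self.masses()
        total = m.sum()
        return (m[0] * o + m[1] * h_local[:, 0] + m[2] * h_local[:, 1]) / total


def assign_water_topology(
    frame: Frame, covalent_bound: float = 1.25, deuterium: bool = False
) -> WaterTopology:
    """Attach each H (or D) to its minimum-image-nearest O.

    Raises :class:`TopologyError` when any O ends up with a number of
    hydrogens other than two, or any assigned O–H distance exceeds
    ``covalent_bound`` (default 1.25 Å — accommodates stretched bonds while
    rejecting H-bond partners at ~1.7–2 Å).
    """
    elems = [e.upper() for e in frame.elements]
    o_idx = [i for i, e in enumerate(elems) if e == "O"]
    h_idx = [i for i, e in enumerate(elems) if e in ("H", "D")]
    if len(o_idx) + len(h_idx) != frame.n_atoms:
        bad = sorted(set(elems) - {"O", "H", "D"})
        raise TopologyError(f"frame contains non-water elements: {bad}")
    if len(h_idx) != 2 * len(o_idx):
        raise TopologyError(
            f"expected 2 H per O, got {len(h_idx)} H for {len(o_idx)} O"
        )

    o_pos = frame.positions[o_idx]
    h_pos = frame.positions[h_idx]
    # minimum-image distance matrix H x O
    d = h_pos[:, None, :] - o_pos[None, :, :]
    d = minimum_image(d, frame.box_edge)
    dist = np.linalg.norm(d, axis=2)
    nearest = np.argmin(dist, axis=1)

    assigned: dict[int, list[int]] = {j: [] for j in range(len(o_idx))}
    errors: list[str] = []
    for hi, oj in enumerate(nearest):
        r = dist[hi, oj]
        if r > covalent_bound:
            errors.append(
                f"H atom {h_idx[hi]} is {r:.3f} Å from nearest O atom "
                f"{o_idx[oj]} (> {covalent_bound} Å)"
            )
        assigned[oj].append(hi)
    for oj, his in assigned.items():
        if len(his) != 2:
            errors.append(
                f"O atom {o_idx[oj]} has {len(his)} assigned H "
                f"(atoms {[h_idx[i] for i in his]})"
            )
    if errors:
        raise TopologyError("; ".join(errors))

    molecules = [
        (o_idx[oj], h_idx[assigned[oj][0]], h_idx[assigned[oj][1]])
        for oj in range(len(o_idx))
    ]
    return WaterTopology(molecules, hydrogen_mass=MASS_D if deuterium else MASS_H)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _validate_xyz_blocks(path: Path) -> None:
    """Check multi-frame XYZ block structure, naming the first bad frame."""
    lines = path.read_text().splitlines()
    i = 0
    frame = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError as exc:
            raise TrajectoryParseError(
                f"malformed XYZ block at frame {frame} in {path}: "
                f"expected atom count, got {lines[i]!r}"
            ) from exc
        body = lines[i + 2: i + 2 + n]
        ok = len(body) == n
        if ok:
            for rec in body:
                parts = rec.split()
                try:
                    ok = len(parts) >= 4 and all(
                        np.isfinite(float(x)) for x in parts[1:4]
                    )
                except ValueError:
                    ok = False
                if not ok:
                    break
        if not ok:
            raise TrajectoryParseError(
                f"malformed XYZ block at frame {frame} in {path}: "
                f"declared {n} atoms"
            )
        i += 2 + n
        frame += 1


def read_xyz_trajectory(
    path: str | Path, box_edge: float, frame_spacing: float | None = None
) -> Trajectory:
    """Read a multi-frame XYZ file (Å) into a :class:`Trajectory`.

    XYZ stores no box, so ``box_edge`` (Å) must be supplied. Parsing is
    delegated to MDAnalysis; malformed frame blocks are reported with the
    offending frame index.
    """
    import MDAnalysis as mda

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if box_edge is None or box_edge <= 0:
        raise ValueError("a positive cubic box_edge is required (XYZ stores none)")

    _validate_xyz_blocks(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MDAnalysis guesses masses noisily
        u = mda.Universe(str(path), format="XYZ", topology_format="XYZ")
        elements = [str(n) for n in u.atoms.names]
        frames = []
        try:
            for ts in u.trajectory:
                frames.append(ts.positions.astype(float).copy())
        except (ValueError, EOFError) as exc:
            raise TrajectoryParseError(
                f"malformed XYZ block at frame {len(frames)} in {path}: {exc}"
            ) from exc
    if not frames:
        raise TrajectoryParseError(f"no frames found in {path}")
    return Trajectory(
        np.stack(frames),
        elements,
        box_edge,
        frame_spacing=frame_spacing,
        metadata={"source": str(path), "format": "xyz"},
    )


def write_xyz_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a standard multi-frame XYZ file with 6-decimal coordinates."""
    import MDAnalysis as mda

    path = Path(path)
    if traj.n_frames == 0:
        path.write_text("")
        return
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(traj.n_atoms, trajectory=True)
        u.add_TopologyAttr("names", traj.elements)
        with mda.coordinates.XYZ.XYZWriter(
            str(path), n_atoms=traj.n_atoms, precision=6, remark=""
        ) as w:
            for i in range(traj.n_frames):
                u.atoms.positions = traj.positions[i]
                w.write(u.atoms)


def read_cpmd_trajectory(
    path: str | Path,
    element_order: Sequence[str],
    box_edge_bohr: float | None = None,
    box_edge: float | None = None,
    frame_spacing: float | None = None,
) -> Trajectory:
    """Read a CPMD-style TRAJECTORY file (atomic units → Å).

    The format is one whitespace-separated line per atom: step index, x, y, z
    and optionally velocities; no element symbols are stored, so
    ``element_order`` supplies them. The box edge may be given in Bohr
    (``box_edge_bohr``) or directly in Å (``box_edge``).

    Non-monotone step indices produce a warning and frames are reordered;
    inconsistent atom counts between steps raise
    :class:`TrajectoryParseError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if box_edge is None:
        if box_edge_bohr is None:
            raise ValueError("supply box_edge (Å) or box_edge_bohr")
        box_edge = box_edge_bohr * BOHR_TO_ANGSTROM

    raw = np.atleast_2d(np.loadtxt(str(path)))
    if raw.size == 0:
        raise TrajectoryParseError(f"no data in {path}")
    if raw.shape[1] < 4:
        raise TrajectoryParseError(
            f"{path}: expected at least 4 columns (step, x, y, z), got {raw.shape[1]}"
        )
    steps = raw[:, 0].astype(int)
    n_atoms = len(element_order)

    blocks: list[tuple[int, np.ndarray]] = []
    i = 0
    while i < len(raw):
        step = steps[i]
        j = i
        while j < len(raw) and steps[j] == step:
            j += 1
        if j - i != n_atoms:
            raise TrajectoryParseError(
                f"step {step}: {j - i} atoms, expected {n_atoms}"
            )
        blocks.append((step, raw[i:j, 1:4] * BOHR_TO_ANGSTROM))
        i = j

    order = [b[0] for b in blocks]
    if sorted(order) != order:
        warnings.warn("non-monotone step indices; frames reordered")
        blocks.sort(key=lambda b: b[0])
    return Trajectory(
        np.stack([b[1] for b in blocks]),
        list(element_order),
        box_edge,
        frame_spacing=frame_spacing,
        metadata={
            "source": str(path),
            "format": "cpmd",
            "steps": [b[0] for b in blocks],
        },
    )
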