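"""Multiple-time-step (impulse r-RESPA) velocity-Verlet integrator.

The propagator splits the force into a cheap *inner* component, applied with
velocity-Verlet at the small step δt, and a slow *outer* correction
F_target − F_inner applied as symmetric half-impulses at the boundaries of
each outer step Δt = n·δt. With n = 1 the scheme reduces exactly to plain
velocity-Verlet on the target force; the impulse form is time-reversible and
symplectic. NVE only — thermostats are out of scope.

Force providers are plug-in callables ``(positions, box_edge) → forces`` in
amu·Å/ps²; an optional matching potential-energy callable enables the
energy-conservation diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .units import AU_TIME_TO_PS

__all__ = [
    "MDState",
    "MTSConfig",
    "ForceProvider",
    "respa_propagate",
    "energy_drift",
    "INNER_STEP_15AU_PS",
]

#: 15 atomic units of time in ps — a typical inner step for water.
INNER_STEP_15AU_PS = 15.0 * AU_TIME_TO_PS

ForceProvider = Callable[[np.ndarray, float], np.ndarray]
EnergyFn = Callable[[np.ndarray, float], float]


@dataclass
class MDState:
    """Positions (Å), velocities (Å/ps), masses (amu), cubic box edge (Å)."""

    positions: np.ndarray
    velocities: np.ndarray
    masses: np.ndarray
    box_edge: float
    time: float = 0.0  # ps

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.velocities = np.atleast_2d(np.asarray(self.velocities, dtype=float))
        self.masses = np.asarray(self.masses, dtype=float)
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have the same shape")
        if len(self.masses) != len(self.positions):
            raise ValueError("one mass per atom required")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")

    def copy(self) -> "MDState":
        return MDState(
            self.positions.copy(),
            self.velocities.copy(),
            self.masses.copy(),
            self.box_edge,
            self.time,
        )

    def kinetic_energy(self) -> float:
        return float(0.5 * np.sum(self.masses[:, None] * self.velocities**2))


@dataclass
class MTSConfig:
    """Inner step δt (ps), outer/inner ratio n, number of outer steps."""

    inner_dt: float = INNER_STEP_15AU_PS
    ratio: int = 1
    n_outer_steps: int = 100
    record_every: int = 1  # outer steps between recorded samples

    def __post_init__(self) -> None:
        if self.inner_dt <= 0:
            raise ValueError("inner_dt must be positive")
        if int(self.ratio) != self.ratio or self.ratio < 1:
            raise ValueError("ratio must be an integer >= 1")


@dataclass
class MTSResult:
    """Recorded trajectory and energy series from a RESPA run."""

    times: np.ndarray  # ps
    positions: np.ndarray  # (n_rec, n_atoms, 3)
    velocities: np.ndarray
    kinetic: np.ndarray
    potential: np.ndarray | None
    total: np.ndarray | None

    def energy_log(self) -> pd.DataFrame:
        data = {"time": self.times, "kinetic": self.kinetic}
        if self.potential is not None:
            data["potential"] = self.potential
            data["total"] = self.total
        return pd.DataFrame(data)


def _check_finite(forces: np.ndarray, step: int) -> None:
    if not np.all(np.isfinite(forces)):
        raise FloatingPointError(f"non-finite force at inner step {step}")


def respa_propagate(
    state: MDState,
    inner_provider: ForceProvider,
    target_provider: ForceProvider | None = None,
    config: MTSConfig | None = None,
    energy_fn: EnergyFn | None = None,
) -> MTSResult:
    """Propagate with the impulse (kick) r-RESPA splitting.

    Outer loop: half-kick with the slow correction F_target − F_inner over
    Δt = n·δt, then n inner velocity-Verlet steps on F_inner, then the
    closing half-kick. ``target_provider=None`` (or identical to the inner
    provider) disables the correction, giving plain velocity-Verlet on the
    inner force. ``energy_fn`` evaluates the target potential for the energy
    log.
    """
    config = config or MTSConfig()
    s = state.copy()
    n = int(config.ratio)
    dt = config.inner_dt
    outer_dt = n * dt
    inv_m = 1.0 / s.masses[:, None]

    def slow_force(pos):
        if target_provider is None:
            return np.zeros_like(pos)
        f = target_provider(pos, s.box_edge) - inner_provider(pos, s.box_edge)
        return f

    f_inner = inner_provider(s.positions, s.box_edge)
    _check_finite(f_inner, 0)
    f_slow = slow_force(s.positions)
    _check_finite(f_slow, 0)

    rec_t, rec_x, rec_v, rec_k, rec_p = [], [], [], [], []

    def record():
        rec_t.append(s.time)
        rec_x.append(s.positions.copy())
        rec_v.append(s.velocities.copy())
        rec_k.append(s.kinetic_energy())
        if energy_fn is not None:
            rec_p.append(float(energy_fn(s.positions, s.box_edge)))

    record()
    step = 0
    for outer in range(config.n_outer_steps):
        # opening half-impulse of the slow correction over the outer step
        s.velocities += 0.5 * outer_dt * f_slow * inv_m
        for _ in range(n):
            step += 1
            s.velocities += 0.5 * dt * f_inner * inv_m
            s.positions += dt * s.velocities
            f_inner = inner_provider(s.positions, s.box_edge)
            _check_finite(f_inner, step)
            s.velocities += 0.5 * dt * f_inner * inv_m
        f_slow = slow_force(s.positions)
        _check_finite(f_slow, step)
        s.velocities += 0.5 * outer_dt * f_slow * inv_m
        s.time += outer_dt
        if (outer + 1) % config.record_every == 0:
            record()

    times = np.array(rec_t)
    kin = np.array(rec_k)
    pot = np.array(rec_p) if energy_fn is not None else None
    tot = kin + pot if pot is not None else None
    return MTSResult(times, np.array(rec_x), np.array(rec_v), kin, pot, tot)


def energy_drift(energy_series: np.ndarray, times: np.ndarray) -> tuple[float, float]:
    """Least-squares linear drift rate (energy/ps) and max absolute deviation.

    The deviation is measured from the series mean.
    """
    e = np.asarray(energy_series, dtype=float)
    t = np.asarray(times, dtype=float)
    if len(e) < 2:
        raise ValueError("need at least 2 energy samples")
    slope = np.polyfit(t, e, 1)[0]
    return float(slope), float(np.max(np.abs(e - e.mean())))
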