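"""Translational and rotational dynamics of water from MD trajectories.

Self-diffusion follows the Einstein relation — D is one sixth of the
long-time slope of the mean-squared displacement of the oxygen atoms,
averaged over molecules and multiple time origins. A finite cubic box with
periodic hydrodynamic self-interaction biases the estimate; the correction

    D_∞ = D_L + ξ·k_B·T / (6π·η·L),    ξ = 2.837297

restores the infinite-size limit given the shear viscosity η. The constant ξ
is the dimensionless self-energy of a point charge in a periodic cubic cell
with neutralizing background; :func:`ewald_self_constant` recomputes it from
scratch by Ewald summation.

Rotational time scales come from orientational autocorrelation functions
C_n(t) = ⟨P_n(û(t₀+t)·û(t₀))⟩ of molecular unit vectors (O–H bonds, the H–H
direction, or the dipole/bisector direction), with P_n the Legendre
polynomial of order 1 or 2. After the initial sub-picosecond librational
decay, C_n is exponential and τ_n is obtained by fitting A·e^(−t/τ); for
isotropic rotational diffusion with constant D_r, τ_n = 1/(n(n+1)·D_r).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import erfc

from .trajectory import Trajectory, WaterTopology, minimum_image
from .units import A2_PER_PS_TO_1E9_M2_S, KB_J_PER_K

__all__ = [
    "MSDResult",
    "DiffusionEstimate",
    "ACFResult",
    "RelaxationTime",
    "XI_CUBIC",
    "ewald_self_constant",
    "unwrap_trajectory",
    "compute_msd",
    "fit_diffusion",
    "finite_size_correct",
    "rescale_exp_to_box",
    "orientational_acf",
    "fit_relaxation_time",
]

#: Dimensionless cubic-lattice (Wigner) constant of the finite-size correction.
XI_CUBIC = 2.837297


def ewald_self_constant(alpha: float = 5.0, n_real: int = 6, n_recip: int = 10) -> float:
    """Recompute ξ by Ewald summation on a unit cubic cell.

    ξ = −ψ(0), where ψ(0) is the potential at a unit point charge due to all
    of its periodic images plus a uniform neutralizing background:

        ψ(0) = Σ'_n erfc(α|n|)/|n| + 4π Σ_{k≠0} e^(−k²/4α²)/k²
               − π/α² − 2α/√π,   k = 2πm.

    Defaults converge well past 6 significant figures.
    """
    rng = np.arange(-max(n_real, n_recip), max(n_real, n_recip) + 1)
    grid = np.stack(np.meshgrid(rng, rng, rng, indexing="ij"), -1).reshape(-1, 3)
    grid = grid[np.any(grid != 0, axis=1)].astype(float)

    r = np.linalg.norm(grid, axis=1)
    real = np.sum(erfc(alpha * r[r <= n_real + 1e-9]) / r[r <= n_real + 1e-9])
    k = 2.0 * np.pi * grid
    k2 = np.sum(k * k, axis=1)
    sel = np.linalg.norm(grid, axis=1) <= n_recip + 1e-9
    recip = 4.0 * np.pi * np.sum(np.exp(-k2[sel] / (4.0 * alpha**2)) / k2[sel])
    psi0 = real + recip - np.pi / alpha**2 - 2.0 * alpha / np.sqrt(np.pi)
    return float(-psi0)


# ---------------------------------------------------------------------------
# Unwrapping and MSD
# ---------------------------------------------------------------------------

def unwrap_trajectory(traj: Trajectory, max_jump_fraction: float = 0.4) -> Trajectory:
    """Remove periodic wrapping by accumulating minimum-image frame-to-frame steps.

    Assumes no atom genuinely moves L/2 or more between saved frames. A
    minimum-imaged step with any component of magnitude ≥
    ``max_jump_fraction``·L is treated as an aliasing hazard and raises,
    naming the frame and atom.
    """
    L = traj.box_edge
    pos = traj.positions
    out = np.empty_like(pos)
    out[0] = pos[0]
    limit = max_jump_fraction * L
    for t in range(1, traj.n_frames):
        step = minimum_image(pos[t] - pos[t - 1], L)
        bad = np.nonzero(np.max(np.abs(step), axis=1) >= limit)[0]
        if len(bad):
            raise ValueError(
                f"suspicious jump >= {limit:.3f} Å at frame {t}, atom {int(bad[0])}"
            )
        out[t] = out[t - 1] + step
    return Trajectory(
        out,
        traj.elements,
        L,
        frame_spacing=traj.frame_spacing,
        metadata={**traj.metadata, "unwrapped": True},
    )


@dataclass
class MSDResult:
    """Mean-squared displacement curve with per-lag origin×molecule sample counts."""

    lag_times: np.ndarray  # ps
    msd: np.ndarray  # Å²
    n_samples: np.ndarray

    def write(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.lag_times, self.msd]),
            fmt="%.6f",
            header="lag(ps)  MSD(A^2)",
        )


def compute_msd(
    traj: Trajectory,
    topology: WaterTopology | None = None,
    max_lag: int | None = None,
    origin_stride: int = 1,
    use_com: bool = False,
) -> MSDResult:
    """Multi-origin MSD of the oxygen atoms (or molecular COMs).

    ``traj`` must be unwrapped. MSD(t) averages |r(t₀+t) − r(t₀)|² over all
    molecules and all origins t₀ on the given stride; lags run from 0 to
    ``max_lag`` frames (default: half the trajectory).
    """
    if traj.n_frames < 2:
        raise ValueError("trajectory must have at least 2 frames")
    if traj.frame_spacing is None:
        raise ValueError("frame_spacing required to express lags in ps")
    if max_lag is None:
        max_lag = traj.n_frames // 2
    max_lag = min(max_lag, traj.n_frames - 1)

    if topology is not None:
        if use_com:
            # COM on unwrapped coordinates: plain mass-weighted mean
            m = topology.masses()
            o = traj.positions[:, topology.oxygen_indices]
            h = traj.positions[:, topology.hydrogen_indices]  # (nf, nm, 2, 3)
            r = (m[0] * o + m[1] * h[:, :, 0] + m[2] * h[:, :, 1]) / m.sum()
        else:
            r = traj.positions[:, topology.oxygen_indices]
    else:
        r = traj.positions

    nf = traj.n_frames
    lags = np.arange(max_lag + 1)
    msd = np.zeros(len(lags))
    counts = np.zeros(len(lags), dtype=int)
    for li, lag in enumerate(lags):
        if lag == 0:
            counts[li] = ((nf - 1) // origin_stride + 1) * r.shape[1]
            continue
        origins = np.arange(0, nf - lag, origin_stride)
        disp = r[origins + lag] - r[origins]
        msd[li] = np.mean(np.sum(disp**2, axis=-1))
        counts[li] = disp.shape[0] * disp.shape[1]
    return MSDResult(lags * traj.frame_spacing, msd, counts)


@dataclass
class DiffusionEstimate:
    """Einstein-relation diffusion coefficient with finite-size bookkeeping."""

    D_L: float  # Å²/ps
    stderr: float  # Å²/ps, from the linear fit
    fit_window: tuple[float, float]  # ps
    D_inf: float | None = None  # Å²/ps, after finite-size correction
    temperature: float | None = None  # K
    box_edge: float | None = None  # Å
    viscosity: float | None = None  # Pa·s

    @property
    def D_L_si(self) -> float:
        """D_L in 10⁻⁹ m²/s."""
        return self.D_L * A2_PER_PS_TO_1E9_M2_S

    @property
    def D_inf_si(self) -> float | None:
        return None if self.D_inf is None else self.D_inf * A2_PER_PS_TO_1E9_M2_S


def fit_diffusion(
    msd: MSDResult, fit_window: tuple[float, float] | None = None
) -> DiffusionEstimate:
    """D_L = slope/6 from an unweighted least-squares line on the MSD window.

    Default window spans 25–75% of the maximum lag, past the ballistic/caging
    regime but where origin statistics are still good.
    """
    tmax = msd.lag_times[-1]
    if fit_window is None:
        fit_window = (0.25 * tmax, 0.75 * tmax)
    lo, hi = fit_window
    sel = (msd.lag_times >= lo) & (msd.lag_times <= hi)
    if np.count_nonzero(sel) < 3:
        raise ValueError("fewer than 3 MSD points in fit window")
    res = stats.linregress(msd.lag_times[sel], msd.msd[sel])
    return DiffusionEstimate(
        D_L=res.slope / 6.0, stderr=res.stderr / 6.0, fit_window=(lo, hi)
    )


def finite_size_correct(
    D_L: float, T: float, L: float, eta: float
) -> float:
    """Infinite-size diffusion coefficient D_∞ = D_L + ξ·k_B·T/(6π·η·L).

    ``D_L`` in Å²/ps, ``T`` in K, ``L`` in Å, ``eta`` in Pa·s; returns Å²/ps.
    """
    if T <= 0 or L <= 0:
        raise ValueError("T and L must be positive")
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    term_m2_s = XI_CUBIC * KB_J_PER_K * T / (6.0 * np.pi * eta * L * 1e-10)
    term_a2_ps = term_m2_s * 1e20 / 1e12  # m²/s → Å²/ps
    return D_L + term_a2_ps


def rescale_exp_to_box(D_inf: float, T: float, L: float, eta: float) -> float:
    """Inverse of :func:`finite_size_correct`: experimental D_∞ → hypothetical D_L."""
    if eta <= 0:
        raise ValueError("viscosity must be positive")
    term_m2_s = XI_CUBIC * KB_J_PER_K * T / (6.0 * np.pi * eta * L * 1e-10)
    return D_inf - term_m2_s * 1e20 / 1e12


# ---------------------------------------------------------------------------
# Orientational relaxation
# ---------------------------------------------------------------------------

_AXES = ("OH", "HH", "dipole")


def _unit_vectors(traj: Trajectory, topology: WaterTopology, axis: str) -> np.ndarray:
    """(n_frames, n_vectors, 3) unit vectors for the requested molecular axis.

    Both O–H bonds are pooled for ``"OH"`` (doubling statistics); ``"dipole"``
    is the HOH-bisector direction, a geometric proxy for μ.
    """
    L = traj.box_edge
    o = traj.positions[:, topology.oxygen_indices]  # (nf, nm, 3)
    h = traj.positions[:, topology.hydrogen_indices]  # (nf, nm, 2, 3)
    b1 = minimum_image(h[:, :, 0] - o, L)
    b2 = minimum_image(h[:, :, 1] - o, L)
    if axis == "OH":
        v = np.concatenate([b1, b2], axis=1)
    elif axis == "HH":
        v = minimum_image(h[:, :, 1] - h[:, :, 0], L)
    elif axis == "dipole":
        v = b1 / np.linalg.norm(b1, axis=-1, keepdims=True) + b2 / np.linalg.norm(
            b2, axis=-1, keepdims=True
        )
    else:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


@dataclass
class ACFResult:
    """Orientational autocorrelation curve C_n(t)."""

    times: np.ndarray  # ps
    values: np.ndarray
    axis: str
    order: int

    def write(self, path) -> None:
        np.savetxt(
            path,
            np.column_stack([self.times, self.values]),
            fmt="%.6f",
            header=f"t(ps)  C_{self.order}^{self.axis}(t)",
        )


def orientational_acf(
    traj: Trajectory,
    topology: WaterTopology,
    axis: str = "OH",
    order: int = 2,
    max_lag: int | None = None,
    origin_stride: int = 1,
) -> ACFResult:
    """C_n(t) = ⟨P_n(û(t₀+t)·û(t₀))⟩ over molecules and time origins.

    P₁(x) = x, P₂(x) = (3x² − 1)/2; ``order`` ∈ {1, 2}.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if traj.frame_spacing is None:
        raise ValueError("frame_spacing required")
    u = _unit_vectors(traj, topology, axis)
    nf = traj.n_frames
    if max_lag is None:
        max_lag = nf // 2
    max_lag = min(max_lag, nf - 1)
    lags = np.arange(max_lag + 1)
    c = np.empty(len(lags))
    c[0] = 1.0
    for li, lag in enumerate(lags[1:], start=1):
        origins = np.arange(0, nf - lag, origin_stride)
        dots = np.sum(u[origins + lag] * u[origins], axis=-1)
        if order == 1:
            c[li] = np.mean(dots)
        else:
            c[li] = np.mean(1.5 * dots**2 - 0.5)
    return ACFResult(lags * traj.frame_spacing, c, axis, order)


@dataclass
class RelaxationTime:
    """Exponential decay constant of an orientational ACF."""

    tau: float  # ps
    amplitude: float
    fit_window: tuple[float, float]  # ps
    residual: float  # RMS residual in log space
    flagged_short: bool = False  # trajectory shorter than ~3·τ


def fit_relaxation_time(
    acf: ACFResult,
    fit_start: float = 1.0,
    fit_end: float | None = None,
    floor: float = 0.05,
) -> RelaxationTime:
    """Fit A·e^(−t/τ) to the exponential regime of an ACF.

    The fit is linear least squares on log C over [fit_start, fit_end],
    skipping the initial librational decay (default 1 ps). ``fit_end``
    defaults to the first time C drops below ``floor`` (or the end of the
    data). Estimates from trajectories shorter than three times the fitted τ
    are flagged as under-converged.
    """
    t, c = acf.times, acf.values
    if fit_end is None:
        below = np.nonzero(c < floor)[0]
        fit_end = t[below[0]] if len(below) else t[-1]
    sel = (t >= fit_start) & (t <= fit_end) & (c > 0)
    if np.count_nonzero(sel) < 3:
        raise ValueError("fewer than 3 positive ACF points in fit window")
    x, y = t[sel], np.log(c[sel])
    res = stats.linregress(x, y)
    if res.slope >= 0:
        raise ValueError("ACF does not decay over the fit window")
    tau = -1.0 / res.slope
    amp = float(np.exp(res.intercept))
    resid = float(np.sqrt(np.mean((y - (res.intercept + res.slope * x)) ** 2)))
    return RelaxationTime(
        tau=float(tau),
        amplitude=amp,
        fit_window=(float(fit_start), float(fit_end)),
        residual=resid,
        flagged_short=t[-1] < 3.0 * tau,
    )
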