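"""Radial distribution functions, first-shell descriptors and coordination numbers.

g(r) is the ratio of the observed pair density at separation r to the
ideal-gas expectation at the same overall density; the O–O coordination
number follows from n = 4πρ* ∫₀^rc r² g_OO(r) dr with ρ* the molecular
number density and rc the first minimum of either r²g(r) (the integrand —
the convention used for comparison with scattering experiments) or g(r)
itself. Binned curves are smoothed by cubic-spline interpolation for
extremum location and integration.

Peak descriptors measured at different simulation temperatures can be
shifted to a common 298 K reference through a least-squares fit to a
user-supplied experimental temperature table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

from .trajectory import Trajectory, WaterTopology, minimum_image

__all__ = [
    "RDFResult",
    "PeakDescriptors",
    "ReferenceTable",
    "compute_rdf",
    "find_first_extrema",
    "coordination_number",
    "rescale_descriptor_to_298K",
]

_PAIRS = ("OO", "OH", "HH")


@dataclass
class RDFResult:
    """Binned pair-correlation curve for one species pair."""

    pair: str
    r: np.ndarray  # bin centres, Å
    g: np.ndarray
    bin_width: float
    number_density: float  # molecular number density ρ*, Å⁻³
    n_frames: int
    box_edge: float

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"r": self.r, "g": self.g})

    def write(self, path) -> None:
        """Two-column plain text (r, g)."""
        np.savetxt(path, np.column_stack([self.r, self.g]), fmt="%.6f",
                   header=f"r(A)  g_{self.pair}(r)")


@dataclass
class PeakDescriptors:
    """First-shell extremum positions/heights of g(r), plus the r²g(r) minimum."""

    r_max1: float
    g_max1: float
    r_min1: float | None
    g_min1: float | None
    r_c: float | None  # first minimum of the integrand r²g(r)
    temperature: float | None = None


@dataclass
class ReferenceTable:
    """Experimental descriptor values on a temperature grid (for 298 K rescaling)."""

    temperature: np.ndarray  # K, strictly increasing
    values: dict[str, np.ndarray]  # descriptor name → values

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        if len(self.temperature) < 2:
            raise ValueError("reference table needs at least two rows")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperatures must be strictly increasing")
        self.values = {k: np.asarray(v, dtype=float) for k, v in self.values.items()}
        for k, v in self.values.items():
            if len(v) != len(self.temperature):
                raise ValueError(f"column {k!r} length mismatch")

    @classmethod
    def from_csv(cls, path) -> "ReferenceTable":
        df = pd.read_csv(path, comment="#")
        tcol = df.columns[0]
        return cls(df[tcol].to_numpy(), {c: df[c].to_numpy() for c in df.columns[1:]})

    @classmethod
    def example(cls) -> "ReferenceTable":
        """The packaged synthetic example table (linear trends, not data)."""
        from importlib.resources import files

        return cls.from_csv(
            files("waterkit.data") / "reference_descriptors_synthetic.csv"
        )


def _pair_indices(topology: WaterTopology, pair: str):
    o = topology.oxygen_indices
    h = topology.hydrogen_indices.ravel()
    if pair == "OO":
        return o, o, True
    if pair == "OH":
        return o, h, False
    if pair == "HH":
        return h, h, True
    raise ValueError(f"pair must be one of {_PAIRS}, got {pair!r}")


def compute_rdf(
    traj: Trajectory,
    topology: WaterTopology,
    pair: str = "OO",
    bin_width: float = 0.01,
    r_max: float | None = None,
    exclude_intramolecular: bool = False,
) -> RDFResult:
    """Minimum-image pair-distance histogram normalised to the ideal-gas shell.

    Normalisation uses the actual pair count for the species pair and the box
    volume, so a uniform system gives g ≡ 1 exactly in expectation. For OH
    and HH the intramolecular pairs are included by default (matching
    experimental curves that show the covalent O–H peak); set
    ``exclude_intramolecular=True`` to drop them.
    """
    L = traj.box_edge
    if r_max is None:
        r_max = L / 2.0
    if r_max > L / 2.0 + 1e-12:
        raise ValueError(f"r_max={r_max} exceeds L/2={L / 2}; minimum image invalid")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")

    idx_a, idx_b, same = _pair_indices(topology, pair)
    edges = np.arange(0.0, r_max + bin_width, bin_width)
    edges = edges[edges <= r_max + 1e-12]
    nbins = len(edges) - 1
    hist = np.zeros(nbins)

    # intramolecular (atom-index) pairs to exclude, as a set of frozensets
    excl: set[frozenset[int]] = set()
    if exclude_intramolecular:
        for o, h1, h2 in topology.molecules:
            excl.update(map(frozenset, [(o, h1), (o, h2), (h1, h2)]))

    if same:
        ai, bi = np.triu_indices(len(idx_a), k=1)
        pa, pb = idx_a[ai], idx_b[bi]
    else:
        pa = np.repeat(idx_a, len(idx_b))
        pb = np.tile(idx_b, len(idx_a))
    if exclude_intramolecular and excl:
        keep = np.array(
            [frozenset((int(x), int(y))) not in excl for x, y in zip(pa, pb)]
        )
        pa, pb = pa[keep], pb[keep]
    n_pairs = len(pa)
    if n_pairs == 0:
        raise ValueError("no pairs to histogram")

    for t in range(traj.n_frames):
        pos = traj.positions[t]
        d = minimum_image(pos[pa] - pos[pb], L)
        r = np.linalg.norm(d, axis=1)
        hist += np.histogram(r, bins=edges)[0]

    V = L**3
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    expected = n_pairs * shell / V  # ideal-gas pair count per bin per frame
    g = hist / (traj.n_frames * expected)
    centres = 0.5 * (edges[:-1] + edges[1:])
    rho_star = topology.n_molecules / V
    return RDFResult(pair, centres, g, bin_width, rho_star, traj.n_frames, L)


def _refine_extremum(spline: CubicSpline, lo: float, hi: float, kind: str) -> float:
    """Root of the spline derivative bracketed in [lo, hi]."""
    dr = spline.derivative()
    roots = dr.roots(extrapolate=False)
    roots = roots[(roots >= lo) & (roots <= hi)]
    if len(roots) == 0:
        return 0.5 * (lo + hi)
    d2 = spline.derivative(2)(roots)
    sel = d2 < 0 if kind == "max" else d2 > 0
    if not np.any(sel):
        return 0.5 * (lo + hi)
    cand = roots[sel]
    # closest to bracket centre
    return float(cand[np.argmin(np.abs(cand - 0.5 * (lo + hi)))])


def _discrete_extrema(y: np.ndarray, order: int):
    """Interior discrete extrema, ignoring flat plateaus (constant windows)."""

    def _keep(idx):
        out = []
        for i in idx:
            if not (0 < i < len(y) - 1):
                continue
            left = y[max(i - order, 0): i]
            right = y[i + 1: i + order + 1]
            if len(left) and len(right) and y[i] > left.min() and y[i] > right.min():
                out.append(int(i))
        return out

    return _keep(argrelextrema(y, np.greater_equal, order=order)[0])


def _first_min_between(y: np.ndarray, start: int, maxima: list[int]) -> int | None:
    """First index attaining the minimum between a peak and the next one.

    The plateau-tolerant rule (first occurrence of the region minimum) makes
    gapped crystalline histograms, where g is exactly zero between shells,
    behave like smooth liquid curves. Returns None when the curve decays
    monotonically to the end of the grid (no interior minimum).
    """
    after = [i for i in maxima if i > start]
    end = after[0] if after else len(y)
    region = y[start + 1: end]
    if len(region) == 0:
        return None
    imin = start + 1 + int(np.argmin(region))
    if not after and imin >= len(y) - 1:
        return None
    return imin


def find_first_extrema(
    rdf: RDFResult,
    min_height: float = 0.5,
    smoothing_window: float = 0.05,
    temperature: float | None = None,
) -> PeakDescriptors:
    """Locate the first maximum/minimum of g(r) and the first minimum of r²g(r).

    Discrete extrema of the binned curve provide brackets; positions are then
    refined on the analytic derivative of a cubic-spline interpolant.
    ``min_height`` rejects noise bumps below that g value when searching for
    the first genuine peak. Raises ``ValueError("no first peak")`` when g is
    monotone or has no interior maximum.
    """
    r, g = rdf.r, rdf.g
    order = max(1, int(round(smoothing_window / rdf.bin_width)))
    all_maxima = _discrete_extrema(g, order)
    maxima = [i for i in all_maxima if g[i] >= min_height]
    if not maxima:
        raise ValueError("no first peak")
    imax = maxima[0]
    spline = CubicSpline(r, g)
    r_max1 = _refine_extremum(spline, r[max(imax - order, 0)], r[min(imax + order, len(r) - 1)], "max")
    g_max1 = float(spline(r_max1))

    # first minimum: first argmin between the first peak and the next one
    r_min1 = g_min1 = None
    imin = _first_min_between(g, imax, all_maxima)
    if imin is not None:
        r_min1 = _refine_extremum(spline, r[max(imin - order, 0)], r[min(imin + order, len(r) - 1)], "min")
        g_min1 = float(spline(r_min1))

    # same search on the integrand r² g(r)
    y2 = r**2 * g
    spline2 = CubicSpline(r, y2)
    max2 = [i for i in _discrete_extrema(y2, order) if g[i] >= min_height]
    r_c = None
    if max2:
        i2 = _first_min_between(y2, max2[0], _discrete_extrema(y2, order))
        if i2 is not None:
            r_c = _refine_extremum(spline2, r[max(i2 - order, 0)], r[min(i2 + order, len(r) - 1)], "min")
    return PeakDescriptors(r_max1, g_max1, r_min1, g_min1, r_c, temperature)


def coordination_number(
    rdf: RDFResult,
    convention: str = "r2g_min",
    cutoff: float | None = None,
    method: str = "shell",
) -> float:
    """Integrate 4πρ* r² g(r) up to the first-shell cutoff.

    ``convention`` selects the upper limit: ``"r2g_min"`` (first minimum of
    the integrand r²g(r) — the convention consistent with scattering
    analyses), ``"g_min"`` (first minimum of g(r)), or ``"fixed"`` with an
    explicit ``cutoff`` in Å.

    ``method="shell"`` (default) integrates bin-wise with exact shell
    volumes, pro-rating the final partial bin — this inverts the RDF
    normalisation exactly, so it reproduces direct neighbour counts even for
    sharply peaked (crystalline) histograms. ``method="spline"`` integrates
    the cubic-spline interpolant of r²g(r); on smooth liquid-like curves the
    two agree to well under 1%.
    """
    if convention == "fixed":
        if cutoff is None:
            raise ValueError("fixed convention requires an explicit cutoff")
        rc = cutoff
    elif convention in ("r2g_min", "g_min"):
        desc = find_first_extrema(rdf)
        rc = desc.r_c if convention == "r2g_min" else desc.r_min1
        if rc is None:
            raise ValueError(f"no first minimum found for convention {convention!r}")
    else:
        raise ValueError(f"unknown convention {convention!r}")
    if rc > rdf.r[-1] + rdf.bin_width:
        raise ValueError(f"cutoff {rc} Å beyond RDF range {rdf.r[-1]} Å")

    pref = 4.0 * np.pi * rdf.number_density
    if method == "spline":
        spline = CubicSpline(rdf.r, rdf.r**2 * rdf.g)
        lo = rdf.r[0]
        head = rdf.g[0] * lo**3 / 3.0  # below the first bin centre
        return float(pref * (head + spline.integrate(lo, rc)))
    if method != "shell":
        raise ValueError(f"unknown method {method!r}")
    lower = rdf.r - rdf.bin_width / 2.0
    upper = rdf.r + rdf.bin_width / 2.0
    hi = np.minimum(upper, rc)
    sel = lower < rc
    shells = (hi[sel] ** 3 - lower[sel] ** 3) / 3.0
    return float(pref * np.sum(shells * rdf.g[sel]))


def rescale_descriptor_to_298K(
    value: float,
    descriptor: str,
    T_sim: float,
    ref_table: ReferenceTable,
    degree: int = 1,
    T_ref: float = 298.0,
) -> float:
    """Shift a peak descriptor measured at T_sim to the 298 K reference.

    A least-squares polynomial (default degree 1) is fitted to the
    experimental temperature dependence of the descriptor; the returned value
    is ``value − fit(T_sim) + fit(T_ref)``, i.e. only the empirical
    temperature trend is removed, not the offset between simulation and
    experiment.
    """
    if descriptor not in ref_table.values:
        raise ValueError(f"descriptor {descriptor!r} not in reference table")
    t = ref_table.temperature
    if not (t[0] - 30.0 <= T_sim <= t[-1] + 30.0):
        warnings.warn(
            f"T_sim={T_sim} K is more than 30 K outside the reference range "
            f"[{t[0]}, {t[-1]}] K; extrapolating"
        )
    coeffs = np.polyfit(t, ref_table.values[descriptor], deg=min(degree, len(t) - 1))
    fit = np.poly1d(coeffs)
    return float(value - fit(T_sim) + fit(T_ref))
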