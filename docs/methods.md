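# Methods

This note documents the models, conventions and numerical choices behind each
analysis stage, what the synthetic generators do and do not emulate, and the
known limitations.

## Conventions and units

All analysis operates in Å and ps; unit conversion happens once, at the I/O
boundary (Bohr → Å with 0.529177210903 for the CPMD-style format, atomic time
units → ps with 2.4188843×10⁻⁵). The minimum-image convention maps every
displacement component into (−L/2, L/2], with the tie at exactly L/2 resolved
to +L/2 so the map is deterministic. Frames are assumed wrapped on input; a
dedicated unwrap pass accumulates minimum-image frame-to-frame steps and is a
precondition for the MSD. The unwrap is only valid when no molecule moves
L/2 or more between saved frames; a step with any component ≥ 0.4·L (the
default guard) aborts with the frame and atom index, since larger genuine
jumps would alias undetectably.

Water topology is assigned geometrically: each H attaches to its
minimum-image-nearest O, with a configurable covalent bound (default 1.25 Å —
loose enough for stretched bonds in ab initio trajectories, tight enough to
reject H-bond partners at 1.7–2 Å). Deuterium is a mass label only;
structural analysis is identical, and the heavier mass enters only through
centre-of-mass conventions and the molar mass used for densities.

## Radial distribution functions

g(r) is a minimum-image pair-distance histogram normalised by the ideal-gas
shell expectation computed from the *actual* pair count of the species pair
(N(N−1)/2 for OO, N_O·N_H for OH) and the box volume, which makes the
uniform-system limit exactly 1. Exact shell volumes 4π(r₂³−r₁³)/3 are used
per bin rather than 4πr²Δr. Intramolecular pairs are included in g_OH/g_HH by
default (the covalent O–H peak is part of the experimental curves); a switch
excludes them.

First-shell descriptors are located in two steps: discrete extrema of the
binned curve (with a plateau filter so flat stretches — exact zeros between
crystalline shells, or the constant baseline of a synthetic curve — are not
spurious extrema) provide brackets, and the position is refined as a root of
the analytic derivative of a not-a-knot cubic spline. The first minimum is
the first point attaining the minimum between the first and second discrete
maxima, which behaves identically for smooth liquid curves and for gapped
crystalline histograms. The same search on the integrand r²g(r) yields the
cutoff r_c used by the coordination number.

The coordination number 4πρ*∫r²g dr, ρ* = N/V, is integrated bin-wise with
exact shell volumes and a pro-rated final bin. This inverts the histogram
normalisation exactly, so on a crystal it reproduces direct neighbour counts
up to the inherent N/(N−1) factor (the histogram is normalised per pair, the
integral multiplies by the full density); a spline-integral alternative is
available and agrees to well under 1% on smooth curves, where doubling the
bin width also moves the result by less than 1%. With 64 molecules the
N/(N−1) factor means a perfect 4-coordinated lattice integrates to 4.063; we
report the formula's value rather than silently rescaling, and tests assert
the lattice invariant at the corresponding 2% level.

Rescaling a descriptor to the 298 K reference removes the empirical
temperature trend: value − fit(T_sim) + fit(298 K), with `fit` a
least-squares polynomial (default degree 1 — the simplest defensible choice;
the degree is a parameter) through a user-supplied temperature table.
Requests more than 30 K outside the table warn. The packaged table is a
synthetic example with realistic signs and magnitudes, for demonstration and
tests only.

## Hydrogen-bond criterion

Two smoothed rectangle functions are multiplied and compared with a 0.5
threshold. Each switch is the rational form

    f(x) = (1 − x²ⁿ) / (1 − x²ᵐ),   x = (d − d₀)/Δ,  n < m,

a total function whose removable singularity at |x| = 1 evaluates to n/m.
The O–O distance switch uses d₀ = 2.8 Å, Δ = 0.45 Å, n = 10, m = 16
(window edge value 0.625); the second switch acts on the path-length excess
d′ = |O_dH| + |HO_a| − |O_dO_a| with d₀ = 0, Δ = 0.4 Å, n = 4, m = 8. d′ is
zero exactly when the bond is collinear and grows monotonically with donor
tilt, so it folds distance and angularity into one metric. The doubled
exponents were chosen over the plain rational (1−xⁿ)/(1−xᵐ) deliberately:
they keep the window symmetric regardless of exponent parity, place the d′
window-edge value n/m = 0.5 exactly at the counting threshold, and make the
d′ switch genuinely rectangle-like — f(0) = 1, f(0.6 Å) ≈ 0.038 — rather
than the long-tailed 1/(1+x⁴). Bond counts are insensitive to this steepness
choice because the product crosses 0.5 at the same geometry either way.

Counting credits each bond to both partners, so a perfect tetrahedral network
gives h = 4 per molecule. The production path finds candidate donor–acceptor
pairs with a periodic KD-tree within d₀ + 2Δ = 3.7 Å (beyond which the first
factor is below 0.016 and no bond is possible); an O(N²) double loop is kept
as an independently coded cross-check and the two are asserted equal
bond-for-bond in the tests.

Angular distributions restrict to first-shell geometries (O–O < 3.4 Å,
H···O < 2.5 Å). β is the donor-side angle between O_d→H and O_d→O_a; the
hydrogen-centred complement α = 180° − ∠(O_d–H–O_a) is reported alongside,
labelled explicitly since conventions differ between studies. Densities are
normalised to unit integral over degrees.

## Dynamics

The MSD averages |r(t₀+t) − r(t₀)|² of the oxygen positions (a COM option
exists) over all molecules and all time origins on a stride (default 1), with
lags to half the trajectory. D_L is slope/6 from an unweighted least-squares
line over a window defaulting to 25–75% of the maximum lag — past the
short-time regime but where origin statistics remain good; the window is a
parameter because no universally correct choice exists. Successive-origin
displacements are correlated, so the reported fit standard error
underestimates the true uncertainty; seed-averaging in the validation suite
addresses this where it matters.

The finite-size correction D_∞ = D_L + ξk_BT/(6πηL) uses ξ = 2.837297, the
dimensionless self-interaction constant of a point charge in a periodic cubic
cell with neutralising background. Rather than hard-coding it blindly, the
package recomputes it by Ewald summation (real-space erfc sum + reciprocal
Gaussian sum − background − self terms) and the tests assert agreement with
the hard-coded constant to 6 significant figures. The inverse map
(experimental D_∞ → finite-box D_L) is provided for comparing simulations
against experiment without a viscosity for the simulated model. Viscosity is
always a user input; computing it (Green–Kubo) is out of scope.

Orientational ACFs C_n(t) = ⟨P_n(û(t₀+t)·û(t₀))⟩ support n = 1, 2 and three
molecular axes: both O–H bonds pooled into one ensemble (doubling
statistics), the H–H direction, and the HOH bisector as a geometric proxy for
the dipole direction (no charges are available from geometry alone).
Relaxation times fit A·e^(−t/τ) by linear least squares on log C over a
window that starts after the initial fast decay (default 1 ps for real water,
where libration dominates the first picosecond; the synthetic rotor has no
libration so its tests fit from 0.2 ps) and ends where C first drops below a
floor. Estimates from trajectories shorter than ~3τ are flagged as
under-converged rather than rejected.

## Equilibrium density

For each snapshot, molecular COMs are rescaled homogeneously with the box
while intramolecular geometry is held rigid (each molecule is first made
whole through minimum-image unwrapping around its COM, then rigidly
translated; output coordinates are molecule-local and not rewrapped, which
all downstream minimum-image analysis handles). A pluggable backend
evaluates E at each scaled volume — analytic backends in the tests, any
external engine in practice. The default scan is 7 points spanning ±6% in
volume; E(V) is interpolated with a not-a-knot cubic spline (exact on
polynomials up to cubic) and minimised on the bracketing interval, falling
back to the exact parabola vertex for 3-point scans. An unbracketed minimum
warns rather than fails. The density is N·M_w/(N_A·V̄_eq) over the snapshot
average (default 30 snapshots, 0.2 ps apart); M_w defaults to H₂O
(18.015 g/mol) with D₂O available.

## Multiple-time-step integrator

The impulse (kick) r-RESPA splitting: the slow correction
F_target − F_inner is applied as symmetric half-impulses at the outer-step
boundaries (Δt = n·δt), with n inner velocity-Verlet steps on F_inner in
between. The symmetric form is time-reversible and symplectic; with n = 1
the scheme is algebraically identical to velocity-Verlet on the target
force, which the tests assert to round-off. NVE only — thermostats are an
equilibration concern outside this package's scope. Energy diagnostics
report the least-squares drift rate and the maximum deviation from the mean;
on a stiff split the deviation grows monotonically with n, which is the
practical criterion for choosing the ratio.

## Synthetic generators: what they do and do not emulate

- **Brownian COM walk** — exact Gaussian steps with per-axis variance
  2·D·dt; rigid monomers, fixed orientation, wrapped positions with the
  unwrapped record kept in metadata. No inertia, no caging, no hydrodynamics:
  it validates the MSD/fit machinery, not water physics.
- **Isotropic rotor** — exponential-map rotations from Gaussian axis-angle
  increments (variance 2·D_r·dt per axis), giving C_n(t) = e^(−n(n+1)D_r t)
  in the small-step limit; COMs fixed on a grid. No libration, so ACFs are
  single-exponential from t = 0.
- **Proton-ordered cubic ice** — oxygens on a diamond sublattice with exact
  nearest-neighbour distance a_OO (default 2.75 Å); hydrogens on the O–O
  axes at the template bond length. The two-in/two-out Bernal–Fowler rules
  are satisfied by orienting the 4-regular bond graph along an Eulerian
  circuit, which cannot fail; the seed shuffles the traversal. This is a
  zero-temperature idealisation: no thermal disorder, no hexagonal stacking.
- **Ideal gas** — uniform independent molecular placements per frame: the
  g ≡ 1 null model. Molecules may overlap by construction.
- **Dimer** — two waters with controllable O–O distance and donor tilt, the
  acceptor oriented to accept; the elementary geometry for switch-function
  and angle tests.
- **Analytic E(V) backends** — quadratic (or arbitrary callable) energy
  landscapes with a known minimum for the density scan.

Passing tests on these generators demonstrates that the estimators recover
known ground truth under their stated assumptions; they say nothing about
force-field or electronic-structure accuracy on real water, where libration,
H-bond kinetics and collective motion are present.

Default monomer geometry is 0.97 Å / 104.5°; only internal consistency
matters for validation, not water realism. Template sites are COM-centred so
generator placements coincide with the mass-weighted centres the analysis
computes.

## Problem sizes used in validation

The validation suite and the reproduction script use 64-molecule systems:
2000-frame Brownian runs (20 ps) and 2000-frame rotor runs (40 ps ≈ 12 τ₂),
averaged over three seeds for quantities with sampling scatter near the
tolerance (a single 20 ps diffusion estimate scatters by ~5%). These sizes
give comfortable statistical margins while keeping the full suite at a few
minutes on one CPU.

## Known limitations

- Cubic boxes only; no triclinic cells, no NpT volume fluctuations.
- XYZ and CPMD-style TRAJECTORY input only; velocities are ignored.
- The dipole axis is the geometric bisector, not a charge-weighted dipole.
- H-bond kinetics (lifetimes, correlation functions) are not computed.
- The reported MSD fit standard error ignores origin correlation.
- The coordination number inherits the N/(N−1) convention mismatch between
  pair-count normalisation and the ρ* = N/V prefactor (≈1.6% at N = 64),
  as discussed above.
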