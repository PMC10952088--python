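"""Unwrapping, Einstein MSD/diffusion, finite-size correction, orientational ACFs."""

import numpy as np
import pytest

from waterkit import (
    ACFResult,
    MSDResult,
    Trajectory,
    XI_CUBIC,
    compute_msd,
    ewald_self_constant,
    finite_size_correct,
    fit_diffusion,
    fit_relaxation_time,
    orientational_acf,
    rescale_exp_to_box,
    unwrap_trajectory,
)
from waterkit.synthetic import grid_topology, rotor_trajectory
from waterkit.units import KB_J_PER_K


class TestUnwrap:
    def test_continuous_trajectory_unchanged(self):
        pos = np.cumsum(np.full((50, 2, 3), 0.05), axis=0)
        traj = Trajectory(pos, ["O", "O"], 100.0, frame_spacing=0.01)
        out = unwrap_trajectory(traj)
        np.testing.assert_allclose(out.positions, pos, atol=1e-12)

    def test_face_crossing_matches_generator_record(self, brownian):
        traj, topo, _ = brownian
        out = unwrap_trajectory(traj)
        record = traj.metadata["unwrapped_com"]
        got = out.positions[:, topo.oxygen_indices]
        # unwrapped paths agree up to the constant image offset of frame 0
        offset = got[0] - record[0]
        np.testing.assert_allclose(got - offset, record, atol=1e-9)

    def test_large_jump_rejected(self):
        L = 10.0
        pos = np.zeros((2, 1, 3))
        pos[1, 0, 0] = 0.6 * L
        traj = Trajectory(pos, ["O"], L, frame_spacing=0.01)
        with pytest.raises(ValueError, match="frame 1, atom 0"):
            unwrap_trajectory(traj)


class TestMSD:
    def test_stationary_is_zero(self):
        traj = Trajectory(np.zeros((20, 3, 3)), ["O"] * 3, 10.0, frame_spacing=0.1)
        msd = compute_msd(traj)
        np.testing.assert_allclose(msd.msd, 0.0)

    def test_ballistic_closed_form(self):
        v = np.array([0.3, -0.4, 0.5])
        t = np.arange(40)[:, None, None] * 0.1
        traj = Trajectory(
            np.broadcast_to(v, (1, 3)) * t, ["O"], 1000.0, frame_spacing=0.1
        )
        msd = compute_msd(traj)
        np.testing.assert_allclose(
            msd.msd, np.dot(v, v) * msd.lag_times**2, rtol=1e-10
        )

    def test_multi_origin_equals_naive_double_loop(self, rng):
        """Oracle equivalence on a 10-frame random walk."""
        pos = np.cumsum(rng.normal(0, 0.3, size=(10, 4, 3)), axis=0)
        traj = Trajectory(pos, ["O"] * 4, 50.0, frame_spacing=0.1)
        msd = compute_msd(traj, max_lag=9)
        for lag in range(1, 10):
            acc, n = 0.0, 0
            for t0 in range(10 - lag):
                for i in range(4):
                    acc += np.sum((pos[t0 + lag, i] - pos[t0, i]) ** 2)
                    n += 1
            assert msd.msd[lag] == pytest.approx(acc / n, rel=1e-12)

    def test_brownian_slope_recovers_diffusion_seed_averaged(self):
        """Einstein-relation recovery: a single 20 ps run of 64 walkers has
        ~5% slope scatter, so the estimate is averaged over seeds."""
        from waterkit.synthetic import brownian_com_trajectory

        D_true, estimates = 0.23, []
        for seed in (101, 202, 303):
            traj = brownian_com_trajectory(64, 12.445, D_true, 0.01, 2000, seed)
            topo = grid_topology(64)
            msd = compute_msd(unwrap_trajectory(traj), topo)
            estimates.append(fit_diffusion(msd).D_L)
        assert np.mean(estimates) == pytest.approx(D_true, rel=0.05)

    def test_too_short_trajectory_rejected(self):
        traj = Trajectory(np.zeros((1, 1, 3)), ["O"], 5.0, frame_spacing=0.1)
        with pytest.raises(ValueError, match="2 frames"):
            compute_msd(traj)


class TestFitDiffusion:
    def test_exact_line(self):
        t = np.linspace(0, 10, 101)
        msd = MSDResult(t, 6 * 0.2 * t, np.ones_like(t, dtype=int))
        est = fit_diffusion(msd)
        assert est.D_L == pytest.approx(0.2, abs=1e-12)
        assert est.stderr == pytest.approx(0.0, abs=1e-10)
        assert est.D_L_si == pytest.approx(2.0)  # Å²/ps → 10⁻⁹ m²/s

    def test_narrow_window_rejected(self):
        t = np.linspace(0, 10, 101)
        msd = MSDResult(t, t.copy(), np.ones_like(t, dtype=int))
        with pytest.raises(ValueError, match="3 MSD points"):
            fit_diffusion(msd, fit_window=(4.0, 4.05))


class TestFiniteSizeCorrection:
    def test_correction_vanishes_at_infinite_viscosity(self):
        d = finite_size_correct(0.2, 300.0, 12.445, eta=1e9)
        assert d == pytest.approx(0.2, abs=1e-12)

    def test_round_trip_identity(self):
        d_inf = finite_size_correct(0.2, 300.0, 12.445, 0.896e-3)
        assert rescale_exp_to_box(d_inf, 300.0, 12.445, 0.896e-3) == pytest.approx(
            0.2, abs=1e-15
        )

    def test_dimensional_analysis_oracle(self):
        """Hand unit conversion: ξk_BT/(6πηL) at T=300 K, L=12.445 Å,
        η=0.896 mPa·s equals 5.591e-10 m²/s = 0.05591 Å²/ps."""
        term_si = XI_CUBIC * KB_J_PER_K * 300.0 / (
            6 * np.pi * 0.896e-3 * 12.445e-10
        )
        assert term_si == pytest.approx(5.5908e-10, rel=1e-4)
        d = finite_size_correct(0.0, 300.0, 12.445, 0.896e-3)
        assert d == pytest.approx(term_si * 1e8, rel=1e-6)  # m²/s → Å²/ps

    def test_monotonicity(self):
        base = finite_size_correct(0.2, 300.0, 12.445, 0.896e-3)
        assert finite_size_correct(0.2, 330.0, 12.445, 0.896e-3) > base
        assert finite_size_correct(0.2, 300.0, 15.0, 0.896e-3) < base
        assert finite_size_correct(0.2, 300.0, 12.445, 1.2e-3) < base

    def test_nonpositive_viscosity_rejected(self):
        with pytest.raises(ValueError, match="viscosity"):
            finite_size_correct(0.2, 300.0, 12.445, 0.0)


class TestEwaldConstant:
    def test_matches_literature_value_to_six_figures(self):
        # the printed constant 2.837297 truncates the true 2.8372975 slightly
        assert ewald_self_constant() == pytest.approx(2.837297, abs=5e-6)
        assert f"{ewald_self_constant():.6g}" == "2.8373"

    def test_independent_of_splitting_parameter(self):
        a = ewald_self_constant(alpha=4.0)
        b = ewald_self_constant(alpha=5.0)
        assert a == pytest.approx(b, abs=1e-8)


class TestOrientationalACF:
    def test_unity_at_zero_lag_and_frozen(self):
        traj = rotor_trajectory(4, 0.0, 0.02, 30, seed=1)
        topo = grid_topology(4)
        for order in (1, 2):
            acf = orientational_acf(traj, topo, "OH", order)
            np.testing.assert_allclose(acf.values, 1.0, atol=1e-12)

    def test_rotor_c2_matches_closed_form(self, rotor):
        traj, topo, D_r = rotor
        acf = orientational_acf(traj, topo, "OH", 2, max_lag=200)
        expected = np.exp(-6 * D_r * acf.times)
        sel = acf.times <= 2.0
        np.testing.assert_allclose(acf.values[sel], expected[sel], atol=0.03)

    def test_global_rotation_invariance(self, rotor):
        from scipy.spatial.transform import Rotation

        traj, topo, _ = rotor
        R = Rotation.from_euler("zyx", [40, 20, 70], degrees=True).as_matrix()
        sub = traj.positions[:200]
        rotated = Trajectory(
            sub @ R.T, traj.elements, traj.box_edge * 10, frame_spacing=traj.frame_spacing
        )
        base = Trajectory(
            sub, traj.elements, traj.box_edge * 10, frame_spacing=traj.frame_spacing
        )
        a = orientational_acf(base, topo, "dipole", 2, max_lag=50)
        b = orientational_acf(rotated, topo, "dipole", 2, max_lag=50)
        np.testing.assert_allclose(a.values, b.values, atol=1e-9)

    def test_axis_validation(self, rotor):
        traj, topo, _ = rotor
        with pytest.raises(ValueError, match="axis"):
            orientational_acf(traj, topo, "NO", 2)
        with pytest.raises(ValueError, match="order"):
            orientational_acf(traj, topo, "OH", 3)


class TestFitRelaxationTime:
    def test_exact_exponential(self):
        t = np.linspace(0, 10, 200)
        acf = ACFResult(t, np.exp(-t / 2.0), "OH", 2)
        rt = fit_relaxation_time(acf, fit_start=0.0)
        assert rt.tau == pytest.approx(2.0, abs=1e-9)
        assert rt.amplitude == pytest.approx(1.0, abs=1e-9)

    def test_amplitude_recovered(self):
        t = np.linspace(0, 12, 200)
        acf = ACFResult(t, 0.9 * np.exp(-t / 3.0), "dipole", 1)
        rt = fit_relaxation_time(acf, fit_start=0.0)
        assert rt.tau == pytest.approx(3.0, abs=1e-9)
        assert rt.amplitude == pytest.approx(0.9, abs=1e-9)

    def test_rotor_tau2_and_legendre_ratio(self, rotor):
        """Isotropic rotational diffusion: τ_n = 1/(n(n+1)D_r), so τ₂ = 3.33 ps
        at D_r = 0.05 ps⁻¹ and τ₁/τ₂ = 3."""
        traj, topo, D_r = rotor
        acf2 = orientational_acf(traj, topo, "OH", 2, max_lag=500)
        tau2 = fit_relaxation_time(acf2, fit_start=0.2, floor=0.2)
        assert tau2.tau == pytest.approx(1 / (6 * D_r), rel=0.10)
        acf1 = orientational_acf(traj, topo, "OH", 1, max_lag=1000)
        tau1 = fit_relaxation_time(acf1, fit_start=0.2, floor=0.2)
        assert tau1.tau / tau2.tau == pytest.approx(3.0, rel=0.15)

    def test_short_trajectory_flagged(self):
        t = np.linspace(0, 2, 50)  # 2 ps of data for τ = 3 ps
        acf = ACFResult(t, np.exp(-t / 3.0), "OH", 2)
        rt = fit_relaxation_time(acf, fit_start=0.0)
        assert rt.flagged_short

    def test_nondecaying_input_rejected(self):
        t = np.linspace(0, 5, 100)
        acf = ACFResult(t, np.ones_like(t), "OH", 2)
        with pytest.raises(ValueError, match="decay"):
            fit_relaxation_time(acf, fit_start=0.0)
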