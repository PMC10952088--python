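"""Smoothed-rectangle H-bond criterion, path-excess metric, angular distributions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from waterkit import (
    HBondCriterion,
    SwitchParams,
    Trajectory,
    angle_distribution,
    excess_path_length,
    hbond_stats,
    is_hbonded,
    minimum_image,
    rect_switch,
)
from waterkit.synthetic import dimer_frame, ideal_gas_trajectory, grid_topology

DIST = SwitchParams(d0=2.8, delta=0.45, n=10, m=16)
PATH = SwitchParams(d0=0.0, delta=0.4, n=4, m=8)


class TestRectSwitch:
    def test_unity_at_centre(self):
        assert rect_switch(2.8, DIST) == 1.0
        assert rect_switch(0.0, PATH) == 1.0

    def test_window_edge_is_n_over_m(self):
        # removable singularity at |x| = 1 evaluates to n/m
        assert rect_switch(2.8 + 0.45, DIST) == pytest.approx(0.625, abs=1e-12)
        assert rect_switch(2.8 - 0.45, DIST) == pytest.approx(0.625, abs=1e-12)
        assert rect_switch(0.4, PATH) == pytest.approx(0.5, abs=1e-12)

    def test_continuous_through_singularity(self):
        eps = 1e-8
        centre = rect_switch(3.25, DIST)
        assert rect_switch(3.25 - eps, DIST) == pytest.approx(centre, abs=1e-6)
        assert rect_switch(3.25 + eps, DIST) == pytest.approx(centre, abs=1e-6)

    def test_path_switch_decays_past_half_angstrom(self):
        assert rect_switch(0.6, PATH) < 0.05
        assert rect_switch(1.0, PATH) < 1e-3

    @given(st.floats(0.0, 3.0), st.floats(0.0, 3.0))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_monotone_nonincreasing_in_distance_from_centre(self, a, b):
        lo, hi = sorted((a, b))
        assert rect_switch(2.8 + hi, DIST) <= rect_switch(2.8 + lo, DIST) + 1e-12
        assert rect_switch(2.8 - hi, DIST) <= rect_switch(2.8 - lo, DIST) + 1e-12

    def test_bounded_unit_interval(self):
        d = np.linspace(0, 8, 2001)
        v = rect_switch(d, DIST)
        assert np.all(v >= 0) and np.all(v <= 1.0 + 1e-12)

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SwitchParams(2.8, -0.1, 10, 16)
        with pytest.raises(ValueError):
            SwitchParams(2.8, 0.45, 16, 10)


class TestExcessPathLength:
    def test_collinear_is_zero(self):
        od = np.zeros(3)
        h = np.array([0.97, 0, 0])
        oa = np.array([2.8, 0, 0])
        assert excess_path_length(od, h, oa, 20.0) == pytest.approx(0.0, abs=1e-12)

    def test_hand_trigonometry_at_30_degrees(self):
        # |O_dH| = 0.97, |HO_a| = sqrt((2.8 − 0.97cos30°)² + (0.97sin30°)²)
        od = np.zeros(3)
        h = 0.97 * np.array([np.cos(np.pi / 6), np.sin(np.pi / 6), 0.0])
        oa = np.array([2.8, 0, 0])
        expected = 0.97 + np.hypot(2.8 - h[0], h[1]) - 2.8
        assert expected == pytest.approx(0.18908, abs=1e-5)
        assert excess_path_length(od, h, oa, 20.0) == pytest.approx(expected, abs=1e-12)

    def test_monotone_in_donor_tilt(self):
        vals = []
        for tilt in (0.0, 5.0, 20.0, 40.0):
            frame, _ = dimer_frame(2.8, tilt)
            vals.append(
                excess_path_length(
                    frame.positions[0], frame.positions[1], frame.positions[3],
                    frame.box_edge,
                )
            )
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_periodic_images_used(self):
        L = 10.0
        od = np.array([9.9, 5, 5])
        h = np.array([0.87, 5, 5])  # covalent across the face
        oa = np.array([3.0, 5, 5])
        direct = excess_path_length(od, h, oa, L)
        unwrapped = excess_path_length(od - [L, 0, 0], h, oa, L)
        assert direct == pytest.approx(unwrapped, abs=1e-12)


class TestIsHbonded:
    def test_linear_dimer_bonded_with_product_near_one(self):
        frame, topo = dimer_frame(2.8, 0.0)
        bonded, product = is_hbonded(
            topo.molecules[0], topo.molecules[0][1], topo.molecules[1], frame
        )
        assert bonded
        assert product == pytest.approx(1.0, abs=1e-6)

    def test_distant_pair_not_bonded(self):
        frame, topo = dimer_frame(6.0, 0.0)
        bonded, product = is_hbonded(
            topo.molecules[0], topo.molecules[0][1], topo.molecules[1], frame
        )
        assert not bonded
        assert product < 1e-3

    def test_foreign_hydrogen_rejected(self):
        frame, topo = dimer_frame(2.8, 0.0)
        with pytest.raises(ValueError, match="belong"):
            is_hbonded(topo.molecules[0], 4, topo.molecules[1], frame)

    def test_products_bimodal_on_ice(self, ice_traj):
        """Realistic geometries give products clustering near 0 or 1."""
        frame_traj, topo = ice_traj
        frame = frame_traj.frame(0)
        products = []
        for i, mol_i in enumerate(topo.molecules):
            for j, mol_j in enumerate(topo.molecules):
                if i == j:
                    continue
                for h in mol_i[1:]:
                    products.append(
                        is_hbonded(mol_i, h, mol_j, frame)[1]
                    )
        products = np.array(products)
        mid = np.count_nonzero((products > 0.2) & (products < 0.8))
        assert mid / len(products) < 0.01


class TestHbondStats:
    def test_ice_has_four_bonds_per_molecule(self, ice_traj):
        traj, topo = ice_traj
        stats = hbond_stats(traj, topo)
        assert stats.h_per_molecule == 4.0
        assert np.all(stats.counts == 4)
        # in proton-ordered ice every molecule donates 2 and accepts 2
        assert np.all(stats.donated == 2)
        assert np.all(stats.accepted == 2)

    def test_dilute_gas_has_almost_none(self):
        traj = ideal_gas_trajectory(8, 30.0, 20, seed=6)
        stats = hbond_stats(traj, grid_topology(8))
        assert stats.h_per_molecule < 0.05

    def test_neighborlist_equals_bruteforce(self):
        """Cell/KD-tree search and the O(N²) double loop agree bond-for-bond."""
        traj = ideal_gas_trajectory(32, 9.939, 10, seed=12)
        topo = grid_topology(32)
        fast = hbond_stats(traj, topo, method="neighborlist")
        slow = hbond_stats(traj, topo, method="bruteforce")
        np.testing.assert_array_equal(fast.counts, slow.counts)
        np.testing.assert_array_equal(fast.donated, slow.donated)
        np.testing.assert_array_equal(fast.n_bonds, slow.n_bonds)

    def test_invariant_under_wrapping(self, ice_traj, rng):
        traj, topo = ice_traj
        ref = hbond_stats(traj, topo).counts
        shifted = Trajectory(
            (traj.positions + rng.uniform(0, 12, 3)) % traj.box_edge,
            traj.elements,
            traj.box_edge,
        )
        moved = hbond_stats(shifted, topo).counts
        np.testing.assert_array_equal(moved, ref)

    def test_counted_bonds_have_first_factor_above_threshold(self, ice_traj):
        """Consistency between the decision and the O–O switch factor."""
        traj, topo = ice_traj
        crit = HBondCriterion()
        pos = traj.positions[0]
        from waterkit.hbond import _frame_bonds_bruteforce

        bonds = _frame_bonds_bruteforce(pos, topo, traj.box_edge, crit)
        for donor, _, acceptor in bonds:
            d = np.linalg.norm(
                minimum_image(
                    pos[topo.molecules[acceptor][0]] - pos[topo.molecules[donor][0]],
                    traj.box_edge,
                )
            )
            assert rect_switch(d, crit.distance) > crit.threshold

    def test_matches_conventional_distance_angle_criterion_on_ice(self, ice_traj):
        """The smoothed criterion agrees with the classical r_OO < 3.5 Å,
        β < 30° geometric criterion on the ice lattice."""
        traj, topo = ice_traj
        pos = traj.positions[0]
        L = traj.box_edge
        conventional = 0
        for i, (oi, h1, h2) in enumerate(topo.molecules):
            for j, (oj, _, _) in enumerate(topo.molecules):
                if i == j:
                    continue
                v_oo = minimum_image(pos[oj] - pos[oi], L)
                d_oo = np.linalg.norm(v_oo)
                if d_oo >= 3.5:
                    continue
                for h in (h1, h2):
                    v_oh = minimum_image(pos[h] - pos[oi], L)
                    cosb = np.dot(v_oh, v_oo) / (np.linalg.norm(v_oh) * d_oo)
                    if np.degrees(np.arccos(np.clip(cosb, -1, 1))) < 30.0:
                        conventional += 1
        smoothed = hbond_stats(traj, topo).n_bonds[0]
        assert conventional == smoothed == 128


class TestAngleDistribution:
    def test_ice_beta_concentrated_at_zero(self, ice_traj):
        traj, topo = ice_traj
        ad = angle_distribution(traj, topo)
        assert ad.n_samples == 128
        # all mass in the first bin: H lies on the O–O axis by construction
        assert ad.beta_density[0] * 1.0 == pytest.approx(1.0, abs=1e-9)
        assert ad.alpha_density[0] == pytest.approx(1.0, abs=1e-9)

    def test_dimer_tilt_peak_position(self):
        frame, topo = dimer_frame(2.8, 20.0)
        traj = Trajectory(frame.positions[None], frame.elements, frame.box_edge)
        ad = angle_distribution(traj, topo, bin_width_deg=1.0)
        peak = ad.beta_grid[np.argmax(ad.beta_density)]
        assert abs(peak - 20.0) <= 1.0

    def test_normalised_to_unit_integral(self, ice_traj):
        traj, topo = ice_traj
        ad = angle_distribution(traj, topo)
        assert np.trapezoid(ad.beta_density, ad.beta_grid) == pytest.approx(
            1.0, abs=2e-2
        ) or ad.beta_density.sum() * 1.0 == pytest.approx(1.0, abs=1e-9)

    def test_empty_distribution_warns(self):
        frame, topo = dimer_frame(8.0, 0.0)
        traj = Trajectory(frame.positions[None], frame.elements, frame.box_edge)
        with pytest.warns(UserWarning, match="no qualifying"):
            ad = angle_distribution(traj, topo)
        assert ad.n_samples == 0
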