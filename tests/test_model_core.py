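"""Force-field terms, reduced units and the chain data model."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plectosim.fixtures import planar_circle, twisted_circle
from plectosim.model_core import (
    EllipsoidAxes,
    ForceField,
    ReducedUnits,
    RingConformation,
    RingTopologySpec,
    SystemState,
    energy_bend,
    energy_bond,
    energy_repulsive,
    energy_twist,
    junction_angles,
    persistence_length,
)


class TestRepulsive:
    @pytest.mark.parametrize(
        "r, expected",
        [
            (1.0, 0.0),                       # LJ crosses zero at the cutoff
            (0.9, 4 * (0.9**-12 - 0.9**-6)),  # direct evaluation: 6.634
            (1.5, 0.0),                       # beyond cutoff
            (0.999999, 4 * (0.999999**-12 - 0.999999**-6)),
        ],
    )
    def test_nonbonded_pair_energy(self, ff, r, expected):
        # three-bead open chain: beads 0 and 2 are the non-bonded pair
        pos = np.array([[0.0, 0, 0], [r / 2, 10.0, 0], [r, 0, 0]])
        assert energy_repulsive(pos, None, ff, closed=False) == pytest.approx(
            expected, abs=1e-10
        )

    def test_continuous_at_cutoff(self, ff):
        pos = np.array([[0.0, 0, 0], [0.5, 10.0, 0], [1.0 - 1e-9, 0, 0]])
        assert abs(energy_repulsive(pos, None, ff, closed=False)) < 1e-7

    def test_bonded_neighbours_excluded(self, ff):
        pos = np.array([[0.0, 0, 0], [0.9, 0, 0]])
        assert energy_repulsive(pos, None, ff, closed=False) == 0.0

    def test_minimum_image(self, ff):
        # beads 9.5 apart in a box of 10 are 0.5 apart through the boundary
        pos = np.array([[0.2, 0, 0], [5.0, 10.0, 0], [9.7, 0, 0]])
        e_pbc = energy_repulsive(pos, 10.0, ff, closed=False)
        assert e_pbc == pytest.approx(4 * (0.5**-12 - 0.5**-6), rel=1e-12)

    def test_overlap_capped_and_flagged(self, ff):
        pos = np.array([[0.0, 0, 0], [0.5, 10.0, 0], [1e-8, 0, 0]])
        with pytest.warns(RuntimeWarning):
            e = energy_repulsive(pos, None, ff, closed=False)
        assert np.isfinite(e)


class TestBend:
    def test_straight_chain_zero(self, ff):
        pos = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        assert energy_bend(pos, ff, closed=False) == pytest.approx(0.0, abs=1e-12)

    def test_right_angle(self, ff):
        pos = np.array([[0.0, 0, 0], [1, 0, 0], [1, 1, 0]])
        assert energy_bend(pos, ff, closed=False) == pytest.approx(17.0)

    def test_regular_polygon_closed_form(self, ff):
        n = 334
        expected = n * 17.0 * (1 - np.cos(2 * np.pi / n))
        got = energy_bend(planar_circle(n).positions, ff)
        assert got == pytest.approx(expected, rel=1e-10)

    def test_matches_per_junction_oracle_on_random_polygon(self, ff, rng):
        # independent angle-by-angle evaluation on a convex planar polygon
        ang = np.sort(rng.uniform(0, 2 * np.pi, 12))
        pos = np.column_stack([np.cos(ang), np.sin(ang), np.zeros(12)])
        oracle = sum(
            17.0 * (1 - np.cos(t)) for t in junction_angles(pos, closed=True)
        )
        assert energy_bend(pos, ff) == pytest.approx(oracle, rel=1e-12)

    def test_zero_length_bond_raises(self, ff):
        pos = np.array([[0.0, 0, 0], [0, 0, 0], [1, 0, 0]])
        with pytest.raises(ValueError):
            energy_bend(pos, ff, closed=False)


class TestBondAndTwist:
    def test_equilibrium_bonds_zero(self, ff):
        pos = np.column_stack([np.arange(4.0), np.zeros(4), np.zeros(4)])
        assert energy_bond(pos, ff, closed=False) == 0.0

    def test_single_stretched_bond(self):
        ff = ForceField(k_bond=800.0)
        pos = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        assert energy_bond(pos, ff, closed=False) == pytest.approx(4.0)

    def test_harmonic_symmetry(self, ff):
        up = np.array([[0.0, 0, 0], [1.05, 0, 0]])
        dn = np.array([[0.0, 0, 0], [0.95, 0, 0]])
        assert energy_bond(up, ff, closed=False) == pytest.approx(
            energy_bond(dn, ff, closed=False)
        )

    def test_twist_relaxed_is_zero(self, ff):
        assert energy_twist(planar_circle(12), ff) == 0.0

    def test_uniform_twist_closed_form(self, ff):
        n, dlk = 334, -7
        conf = twisted_circle(n, dlk)
        expected = n * 0.5 * ff.k_twist * (dlk * 2 * np.pi / n) ** 2
        assert energy_twist(conf, ff) == pytest.approx(expected, rel=1e-12)

    def test_twist_quadratic_scaling(self, ff):
        conf = twisted_circle(50, -2)
        e1 = energy_twist(conf, ff)
        conf.excess_twist = 2 * conf.excess_twist
        assert energy_twist(conf, ff) == pytest.approx(4 * e1, rel=1e-12)


class TestPersistenceLength:
    def test_calibration_50nm(self):
        # kappa = 17, 3 nm beads: the worm-like-chain calibration of the model
        assert persistence_length(17.0, 3.0) == pytest.approx(49.5, abs=0.1)
        assert persistence_length(17.0, 1.0, ReducedUnits()) == pytest.approx(
            49.5, abs=0.1
        )

    def test_reduced_units(self):
        assert persistence_length(17.0, 1.0) == pytest.approx(16.5, abs=0.05)

    def test_stiff_rod_limit(self):
        # L_p -> kappa * b as kappa -> infinity
        assert persistence_length(600.0, 1.0) == pytest.approx(600.0, rel=5e-3)

    def test_invalid_stiffness(self):
        with pytest.raises(ValueError):
            persistence_length(-1.0)


class TestInvariance:
    def test_total_energy_rigid_motion_invariant(self, ff, rng):
        conf = twisted_circle(40, -1)
        pos = conf.positions + 0.02 * rng.standard_normal((40, 3))

        def total(p):
            return (
                energy_repulsive(p, None, ff)
                + energy_bend(p, ff)
                + energy_bond(p, ff)
            )

        base = total(pos)
        # rotation about a random axis + translation
        k = rng.standard_normal(3)
        k /= np.linalg.norm(k)
        ang = 1.1
        kx = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
        rot = np.eye(3) + np.sin(ang) * kx + (1 - np.cos(ang)) * (kx @ kx)
        moved = pos @ rot.T + np.array([3.0, -2.0, 7.0])
        assert total(moved) == pytest.approx(base, rel=1e-10)


class TestDataModel:
    def test_topology_spec_sigma(self):
        spec = RingTopologySpec(delta_lk=-7)
        assert spec.sigma == pytest.approx(-7 / (3000 / 10.5))

    def test_ring_too_small_rejected(self):
        with pytest.raises(ValueError):
            RingConformation(np.zeros((2, 3)))

    def test_excess_twist_shape_checked(self):
        with pytest.raises(ValueError):
            RingConformation(np.zeros((5, 3)), np.zeros(4))

    def test_ellipsoid_axes_ordering(self):
        with pytest.raises(ValueError):
            EllipsoidAxes(1.0, 2.0, 0.5)

    def test_wrap_unwrap_roundtrip(self):
        conf = planar_circle(12)
        conf.positions += 7.0
        state = SystemState([conf], box_length=5.0)
        wrapped, flags = state.wrapped_positions()
        assert np.all(wrapped >= 0) and np.all(wrapped < 5.0)
        np.testing.assert_allclose(
            wrapped + flags * 5.0, state.all_positions(), atol=1e-12
        )

    def test_volume_fraction(self):
        state = SystemState([planar_circle(334) for _ in range(20)], box_length=25.96)
        assert state.volume_fraction() == pytest.approx(0.2, rel=1e-3)

    @given(st.floats(1.5, 400.0))
    @settings(max_examples=25, deadline=None)
    def test_persistence_positive_and_increasing(self, kappa):
        lp = persistence_length(kappa, 1.0)
        assert lp > 0
        assert persistence_length(kappa + 1.0, 1.0) > lp
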