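"""Force terms: -grad E correctness, custom/standard equivalence, OBC."""

import numpy as np
import pytest

from conftest import assert_forces_match_fd, finite_difference_forces

from minimm.forces import (
    CustomAngleTerm,
    CustomBondTerm,
    CustomCentroidBondTerm,
    CustomCompoundBondTerm,
    CustomExternalTerm,
    CustomNonbondedTerm,
    CustomTorsionTerm,
    HarmonicAngleTerm,
    HarmonicBondTerm,
    NonbondedParams,
    NonbondedTerm,
    OBCTerm,
    PeriodicTorsionTerm,
)
from minimm.geometry import box_from_geometry
from minimm.system import COULOMB_CONSTANT


def random_gas(rng, n, scale=0.4):
    """Random positions with a minimum separation to avoid singularities."""
    while True:
        pos = rng.normal(size=(n, 3)) * scale
        d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
        np.fill_diagonal(d, 1.0)
        if d.min() > 0.08:
            return pos


def make_terms(rng):
    """One instance of every interparticle term type on 6 atoms."""
    q = rng.uniform(-0.5, 0.5, 6)
    sig = rng.uniform(0.1, 0.2, 6)
    eps = rng.uniform(0.05, 0.3, 6)
    return [
        HarmonicBondTerm([(0, 1, 300.0, 0.15), (2, 3, 250.0, 0.12)]),
        HarmonicAngleTerm([(0, 1, 2, 60.0, 1.8), (1, 2, 3, 45.0, 2.1)]),
        PeriodicTorsionTerm([(0, 1, 2, 3, 5.0, 2, 0.7), (1, 2, 3, 4, 3.0, 3, 3.1)]),
        NonbondedTerm(NonbondedParams(q, sig, eps,
                                      exceptions=[(0, 3, 0.02, 0.15, 0.1)],
                                      exclusions=[(0, 1), (1, 2)])),
        OBCTerm(q, rng.uniform(0.12, 0.2, 6), rng.uniform(0.7, 0.9, 6)),
        CustomBondTerm("kb*exp(-r/l)", ["kb", "l"], [((0, 2), (4.0, 0.3))]),
        CustomAngleTerm("k*(theta-t0)^2", ["k", "t0"], [((0, 1, 2), (30.0, 1.7))]),
        CustomTorsionTerm("k*(1+cos(2*theta-g))", ["k", "g"],
                          [((0, 1, 2, 3), (2.0, 0.4))]),
        CustomNonbondedTerm("a1*a2/r^4", ["a"], [(0.1,)] * 6),
        CustomCompoundBondTerm(
            "kk*(distance(p1,p2)-angle(p2,p3,p4))^2+cos(dihedral(p1,p2,p3,p4))",
            4, ["kk"], [((0, 1, 2, 3), (1.5,))]),
        CustomCentroidBondTerm(
            "kg*distance(g1,g2)^2", [([0, 1], [1.0, 2.0]), ([2, 3, 4], [1.0, 1.0, 1.0])],
            ["kg"], [((0, 1), (8.0,))]),
    ]


class TestGradientCorrectness:
    def test_every_term_matches_finite_differences(self, rng):
        terms = make_terms(rng)
        for term in terms:
            for _ in range(20):
                assert_forces_match_fd(term, random_gas(rng, 6), rtol=1e-4)

    def test_external_term(self, rng):
        term = CustomExternalTerm("x^2+3*y", [], [(0, ()), (2, ())])
        for _ in range(20):
            assert_forces_match_fd(term, rng.normal(size=(3, 3)))

    def test_interparticle_terms_conserve_force_and_torque(self, rng):
        for term in make_terms(rng):
            pos = random_gas(rng, 6)
            _, f = term.energy_and_forces(pos)
            assert np.abs(f.sum(axis=0)).max() < 1e-9
            torque = np.cross(pos, f).sum(axis=0)
            assert np.abs(torque).max() < 1e-9

    def test_translation_invariance(self, rng):
        shift = np.array([1.7, -0.3, 2.9])
        for term in make_terms(rng):
            pos = random_gas(rng, 6)
            e0, _ = term.energy_and_forces(pos)
            e1, _ = term.energy_and_forces(pos + shift)
            assert e1 == pytest.approx(e0, rel=1e-10, abs=1e-12)


class TestCustomVsStandard:
    def test_bond(self, rng):
        for _ in range(100):
            pos = rng.normal(size=(2, 3))
            k, r0 = rng.uniform(50, 500), rng.uniform(0.1, 0.3)
            std = HarmonicBondTerm([(0, 1, k, r0)])
            cus = CustomBondTerm("0.5*kk*(r-r0)^2", ["kk", "r0"],
                                 [((0, 1), (2 * k, r0))])
            e1, f1 = std.energy_and_forces(pos)
            e2, f2 = cus.energy_and_forces(pos)
            assert e2 == pytest.approx(e1, rel=1e-10, abs=1e-12)
            assert np.abs(f1 - f2).max() < 1e-8 * max(1, np.abs(f1).max())

    def test_angle_example_90_degrees(self):
        pos = np.array([[1.0, 0, 0], [0, 0, 0], [0, 1, 0]])
        term = CustomAngleTerm("k*(theta-theta0)^2", ["k", "theta0"],
                               [((0, 1, 2), (1.0, 0.0))])
        e, _ = term.energy_and_forces(pos)
        assert e == pytest.approx((np.pi / 2) ** 2, rel=1e-12)

    def test_angle(self, rng):
        for _ in range(20):
            pos = random_gas(rng, 3)
            k, t0 = rng.uniform(10, 100), rng.uniform(1.0, 2.5)
            std = HarmonicAngleTerm([(0, 1, 2, k, t0)])
            cus = CustomAngleTerm("k*(theta-t0)^2", ["k", "t0"],
                                  [((0, 1, 2), (k, t0))])
            e1, f1 = std.energy_and_forces(pos)
            e2, f2 = cus.energy_and_forces(pos)
            assert e2 == pytest.approx(e1, rel=1e-10)
            assert np.abs(f1 - f2).max() < 1e-8 * max(1, np.abs(f1).max())

    def test_torsion(self, rng):
        for _ in range(20):
            pos = random_gas(rng, 4)
            k, g = rng.uniform(1, 10), rng.uniform(0, 2 * np.pi)
            std = PeriodicTorsionTerm([(0, 1, 2, 3, k, 3, g)])
            cus = CustomTorsionTerm("k*(1+cos(3*theta-g))", ["k", "g"],
                                    [((0, 1, 2, 3), (k, g))])
            e1, f1 = std.energy_and_forces(pos)
            e2, f2 = cus.energy_and_forces(pos)
            assert e2 == pytest.approx(e1, rel=1e-10, abs=1e-12)
            assert np.abs(f1 - f2).max() < 1e-8 * max(1, np.abs(f1).max())

    def test_lennard_jones_30_particle_gas(self, rng):
        n = 30
        pos = random_gas(rng, n, scale=0.6)
        sig = rng.uniform(0.1, 0.25, n)
        eps = rng.uniform(0.1, 0.8, n)
        std = NonbondedTerm(NonbondedParams(np.zeros(n), sig, eps))
        cus = CustomNonbondedTerm(
            "4*eps*((sig/r)^12-(sig/r)^6); sig=0.5*(sig1+sig2); "
            "eps=sqrt(eps1*eps2)",
            ["sig", "eps"], np.column_stack([sig, eps]))
        e1, f1 = std.energy_and_forces(pos)
        e2, f2 = cus.energy_and_forces(pos)
        assert e2 == pytest.approx(e1, rel=1e-10)
        assert np.abs(f1 - f2).max() < 1e-8 * max(1, np.abs(f1).max())

    def test_compound_reproduces_harmonic_angle(self, rng):
        for _ in range(10):
            pos = random_gas(rng, 3)
            std = HarmonicAngleTerm([(0, 1, 2, 42.0, 1.9)])
            cus = CustomCompoundBondTerm("k*(angle(p1,p2,p3)-t0)^2", 3,
                                         ["k", "t0"], [((0, 1, 2), (42.0, 1.9))])
            e1, f1 = std.energy_and_forces(pos)
            e2, f2 = cus.energy_and_forces(pos)
            assert e2 == pytest.approx(e1, rel=1e-10)
            assert np.abs(f1 - f2).max() < 1e-8 * max(1, np.abs(f1).max())

    def test_centroid_singleton_groups_reduce_to_compound(self, rng):
        pos = random_gas(rng, 4)
        compound = CustomCompoundBondTerm("distance(p1,p2)^2", 2, [],
                                          [((0, 3), ())])
        centroid = CustomCentroidBondTerm("distance(g1,g2)^2",
                                          [([0], [1.0]), ([3], [1.0])],
                                          [], [((0, 1), ())])
        e1, f1 = compound.energy_and_forces(pos)
        e2, f2 = centroid.energy_and_forces(pos)
        assert e2 == pytest.approx(e1, rel=1e-12)
        assert np.allclose(f1, f2, atol=1e-12)

    def test_centroid_equal_mass_pairs_split_force_evenly(self):
        pos = np.array([[0.0, 0, 0], [0, 0.2, 0], [1.0, 0, 0], [1.0, 0.2, 0]])
        term = CustomCentroidBondTerm("distance(g1,g2)",
                                      [([0, 1], [1.0, 1.0]), ([2, 3], [1.0, 1.0])],
                                      [], [((0, 1), ())])
        _, f = term.energy_and_forces(pos)
        assert np.allclose(f[0], f[1])
        assert np.allclose(f[2], f[3])
        assert np.allclose(f[0], [0.5, 0, 0])


class TestStandardNonbonded:
    def test_coulomb_constant(self):
        params = NonbondedParams([1.0, 1.0], [0.1, 0.1], [0.0, 0.0])
        term = NonbondedTerm(params)
        pos = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        e, _ = term.energy_and_forces(pos)
        assert e == pytest.approx(COULOMB_CONSTANT, rel=1e-12)

    def test_lj_zero_at_sigma(self):
        params = NonbondedParams([0.0, 0.0], [0.3, 0.3], [1.0, 1.0])
        term = NonbondedTerm(params)
        pos = np.array([[0.0, 0, 0], [0.3, 0, 0]])
        e, _ = term.energy_and_forces(pos)
        assert e == pytest.approx(0.0, abs=1e-12)

    def test_exception_replaces_pair(self):
        params = NonbondedParams([1.0, 1.0], [0.3, 0.3], [0.5, 0.5],
                                 exceptions=[(0, 1, 0.0, 0.3, 0.0)])
        term = NonbondedTerm(params)
        pos = np.array([[0.0, 0, 0], [0.5, 0, 0]])
        e, _ = term.energy_and_forces(pos)
        assert e == 0.0

    def test_exclusion_contributes_nothing(self):
        params = NonbondedParams([1.0, -1.0], [0.3, 0.3], [0.5, 0.5],
                                 exclusions=[(0, 1)])
        e, f = NonbondedTerm(params).energy_and_forces(
            np.array([[0.0, 0, 0], [0.4, 0, 0]]))
        assert e == 0.0 and np.all(f == 0)

    def test_duplicate_exception_rejected(self):
        with pytest.raises(ValueError):
            NonbondedParams([0, 0], [0.1, 0.1], [0, 0],
                            exceptions=[(0, 1, 0, 0.1, 0), (1, 0, 0, 0.1, 0)])

    def test_pair_beyond_cutoff_contributes_zero(self):
        params = NonbondedParams([0.0, 0.0], [0.3, 0.3], [1.0, 1.0])
        term = NonbondedTerm(params, cutoff=0.9)
        e, f = term.energy_and_forces(np.array([[0.0, 0, 0], [1.0, 0, 0]]))
        assert e == 0.0 and np.all(f == 0)

    def test_cutoff_larger_than_half_box_rejected(self):
        params = NonbondedParams([0.0, 0.0], [0.3, 0.3], [1.0, 1.0])
        term = NonbondedTerm(params, cutoff=1.5, periodic=True)
        box = box_from_geometry("cube", 2.0)
        with pytest.raises(ValueError):
            term.energy_and_forces(np.zeros((2, 3)), box)

    def test_periodic_minimum_image(self):
        box = box_from_geometry("cube", 2.0)
        params = NonbondedParams([1.0, 1.0], [0.1, 0.1], [0.0, 0.0])
        term = NonbondedTerm(params, periodic=True)
        e, _ = term.energy_and_forces(np.array([[0.1, 0, 0], [1.9, 0, 0]]), box)
        # nearest image is 0.2 nm away, not 1.8
        assert e == pytest.approx(COULOMB_CONSTANT / 0.2, rel=1e-12)


class TestOBC:
    def test_single_particle_self_energy_closed_form(self):
        # isolated particle: Born radius equals the offset radius, and the
        # energy is the Born self-energy -k_e (1 - 1/eps_w) q^2 / (2 B)
        term = OBCTerm([1.0], [0.15], [0.8])
        B, *_ = term.born_radii(np.zeros((1, 3)))
        assert B[0] == pytest.approx(0.15 - 0.009, rel=1e-12)
        e, _ = term.energy_and_forces(np.zeros((1, 3)))
        expected = -COULOMB_CONSTANT * (1 - 1 / 78.5) / (2 * B[0])
        assert e == pytest.approx(expected, rel=1e-12)

    def test_distant_charges_approach_sum_of_self_energies(self):
        term = OBCTerm([1.0, -1.0], [0.15, 0.18], [0.8, 0.8])
        e_far, _ = term.energy_and_forces(np.array([[0.0, 0, 0], [5000.0, 0, 0]]))
        selves = sum(
            OBCTerm([q], [r], [0.8]).energy_and_forces(np.zeros((1, 3)))[0]
            for q, r in [(1.0, 0.15), (-1.0, 0.18)])
        # the cross term decays as 1/r; at 5000 nm it is ~0.03 kJ/mol
        assert e_far == pytest.approx(selves, abs=0.05)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            OBCTerm([0.0], [0.0], [0.8])

    def test_matches_independent_reference(self, rng):
        from minimm.fixtures import _reference_obc
        n = 10
        pos = random_gas(rng, n)
        q = rng.uniform(-0.8, 0.8, n)
        R = rng.uniform(0.12, 0.2, n)
        S = rng.uniform(0.7, 0.9, n)
        for sa in (False, True):
            term = OBCTerm(q, R, S, sa_term=sa)
            e, _ = term.energy_and_forces(pos)
            ref = _reference_obc(
                {"charges": q, "radii": R, "screen": S, "sa": sa}, pos)
            assert e == pytest.approx(ref, rel=1e-12)

    def test_forces_match_finite_differences_tightly(self, rng):
        n = 8
        term = OBCTerm(rng.uniform(-0.8, 0.8, n), rng.uniform(0.12, 0.2, n),
                       rng.uniform(0.7, 0.9, n))
        pos = random_gas(rng, n)
        fd = finite_difference_forces(term, pos, h=1e-6)
        _, f = term.energy_and_forces(pos)
        assert np.abs(f - fd).max() / max(1, np.abs(fd).max()) < 1e-6


class TestErrors:
    def test_unknown_expression_variable(self):
        with pytest.raises(ValueError, match="unknown variables"):
            CustomBondTerm("k*r+zap", ["k"], [])

    def test_parameter_width_mismatch(self):
        with pytest.raises(ValueError, match="width mismatch"):
            CustomBondTerm("k*r", ["k"], [((0, 1), (1.0, 2.0))])

    def test_torsion_periodicity_below_one(self):
        with pytest.raises(ValueError):
            PeriodicTorsionTerm([(0, 1, 2, 3, 1.0, 0, 0.0)])

    def test_compound_slot_out_of_range(self):
        with pytest.raises(ValueError, match="slot"):
            CustomCompoundBondTerm("distance(p1,p5)", 2, [], [])

    def test_centroid_zero_weight_rejected(self):
        with pytest.raises(ValueError):
            CustomCentroidBondTerm("distance(g1,g2)",
                                   [([0], [0.0]), ([1], [1.0])], [], [])
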