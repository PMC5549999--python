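"""Integrator DSL, built-in programs, SHAKE/RATTLE."""

import numpy as np
import pytest
from scipy import stats

from minimm.forces import CustomExternalTerm, NonbondedParams, NonbondedTerm
from minimm.integrate import (
    Integrator,
    IntegratorProgram,
    StepOp,
    execute_step,
    langevin_program,
    leapfrog_program,
    rattle_velocities,
    shake_positions,
)
from minimm.system import KB, ConstraintDef, State, System


class ConstantForce:
    """Uniform unit force along +x (test stand-in, not a physical term)."""

    category = "Other"

    def energy_and_forces(self, pos, box=None):
        f = np.zeros_like(pos)
        f[:, 0] = 1.0
        return float(-pos[:, 0].sum()), f


class ZeroForce:
    category = "Other"

    def energy_and_forces(self, pos, box=None):
        return 0.0, np.zeros_like(pos)


class TestDslSemantics:
    def test_leapfrog_on_constant_force_gives_exact_integers(self):
        # unit mass, unit force, dt=1, from rest:
        # v <- v + dt f/m ; x <- x + dt v   =>  (1,1) then (2,3)
        system = System(np.array([1.0]), force_terms=[ConstantForce()])
        integ = Integrator(leapfrog_program(1.0), system, State(np.zeros((1, 3))))
        integ.step(1)
        assert integ.ctx.v[0, 0] == 1.0 and integ.ctx.x[0, 0] == 1.0
        integ.step(1)
        assert integ.ctx.v[0, 0] == 2.0 and integ.ctx.x[0, 0] == 3.0

    def test_global_counter_increments(self):
        prog = IntegratorProgram(step_size=0.5)
        prog.add_global_variable("t", 0.0)
        prog.add_compute_global("t", "t + dt")
        system = System(np.array([1.0]), force_terms=[ZeroForce()])
        integ = Integrator(prog, system, State(np.zeros((1, 3))))
        integ.step(4)
        assert integ.ctx.globals["t"] == 2.0

    def test_compute_sum_over_dofs(self):
        prog = IntegratorProgram(step_size=1.0)
        prog.add_global_variable("twoKE", 0.0)
        prog.add_compute_sum("twoKE", "m*v*v")
        system = System(np.array([2.0, 1.0]), force_terms=[ZeroForce()])
        st = State(np.zeros((2, 3)), np.array([[1.0, 0, 0], [0, 2.0, 0]]))
        integ = Integrator(prog, system, st)
        integ.step(1)
        assert integ.ctx.globals["twoKE"] == 6.0

    def test_if_and_while_blocks(self):
        prog = IntegratorProgram(step_size=1.0)
        prog.add_global_variable("n", 0.0)
        prog.add_global_variable("flag", 1.0)
        prog.steps.append(StepOp("if_block", condition=("flag", ">", "0"),
                                 body=[StepOp("compute_global", "n", "n+1")]))
        prog.steps.append(StepOp("while_block", condition=("n", "<", "5"),
                                 body=[StepOp("compute_global", "n", "n+1")]))
        system = System(np.array([1.0]), force_terms=[ZeroForce()])
        integ = Integrator(prog, system, State(np.zeros((1, 3))))
        integ.step(1)
        assert integ.ctx.globals["n"] == 5.0

    def test_while_iteration_cap(self):
        prog = IntegratorProgram(step_size=1.0)
        prog.add_global_variable("n", 0.0)
        prog.steps.append(StepOp("while_block", condition=("n", ">=", "0"),
                                 body=[StepOp("compute_global", "n", "n+1")]))
        system = System(np.array([1.0]), force_terms=[ZeroForce()])
        with pytest.raises(RuntimeError, match="iterations"):
            Integrator(prog, system, State(np.zeros((1, 3)))).step(1)

    def test_unbound_variable_raises(self):
        prog = IntegratorProgram(step_size=1.0)
        prog.add_compute_per_dof("v", "v + nosuch")
        system = System(np.array([1.0]), force_terms=[ZeroForce()])
        with pytest.raises(NameError):
            Integrator(prog, system, State(np.zeros((1, 3)))).step(1)

    def test_builtin_shadowing_rejected(self):
        prog = IntegratorProgram(step_size=1.0)
        with pytest.raises(ValueError):
            prog.add_global_variable("dt", 0.0)

    def test_execute_step_function(self):
        system = System(np.array([1.0]), force_terms=[ConstantForce()])
        out = execute_step(leapfrog_program(1.0), system, State(np.zeros((1, 3))))
        assert out.positions[0, 0] == 1.0

    def test_forces_lazily_recomputed_after_position_write(self):
        # velocity-Verlet needs fresh forces for its second half-kick
        prog = IntegratorProgram(step_size=0.1)
        prog.add_compute_per_dof("v", "v+0.5*dt*f/m")
        prog.add_compute_per_dof("x", "x+dt*v")
        prog.add_compute_per_dof("v", "v+0.5*dt*f/m")
        term = CustomExternalTerm("x^2", [], [(0, ())])
        system = System(np.array([1.0]), force_terms=[term])
        integ = Integrator(prog, system, State(np.array([[1.0, 0, 0]])))
        integ.step(1)
        # hand-rolled velocity Verlet for the quadratic well
        x, v = 1.0, 0.0
        f = -2 * x
        v += 0.05 * f
        x += 0.1 * v
        f = -2 * x
        v += 0.05 * f
        assert integ.ctx.x[0, 0] == pytest.approx(x, abs=1e-15)
        assert integ.ctx.v[0, 0] == pytest.approx(v, abs=1e-15)


class TestLeapfrog:
    def test_harmonic_oscillator_energy_band_and_no_secular_drift(self):
        # unit mass/stiffness oscillator, dt=0.05, 1e4 steps: bounded energy
        # oscillation (band ~ c dt^2 with measured c ~ 11) and a regression
        # slope consistent with zero secular drift
        term = CustomExternalTerm("0.5*(x^2+y^2+z^2)", [], [(0, ())])
        system = System(np.array([1.0]), force_terms=[term])
        integ = Integrator(leapfrog_program(0.05), system,
                           State(np.array([[1.0, 0, 0]])))
        energies = []
        for _ in range(10000):
            integ.step(1)
            s = integ.state()
            energies.append(s.potential_energy + s.kinetic_energy)
        energies = np.array(energies)
        band = np.abs(energies - energies[0]).max() / abs(energies[0])
        assert band <= 15 * 0.05**2
        slope = stats.linregress(np.arange(10000) * 0.05, energies).slope
        assert abs(slope) <= 5e-7

    def test_constrained_diatomic_holds_bond_length_every_step(self):
        params = NonbondedParams([0.2, -0.2], [0.3, 0.3], [0.4, 0.4],
                                 exclusions=[(0, 1)])
        system = System(np.array([12.0, 12.0]),
                        constraints=[ConstraintDef(0, 1, 0.15)],
                        force_terms=[ConstantForce()])
        st = State(np.array([[0.0, 0, 0], [0.0, 0, 0.15]]),
                   np.array([[0.01, 0.02, 0], [-0.01, 0, 0.03]]))
        integ = Integrator(leapfrog_program(0.002), system, st)
        for _ in range(50):
            integ.step(1)
            d = np.linalg.norm(integ.ctx.x[0] - integ.ctx.x[1])
            assert abs(d - 0.15) / 0.15 < 1e-7

    def test_final_velocity_rule_is_position_difference_over_dt(self):
        system = System(np.array([2.0]), force_terms=[ConstantForce()])
        integ = Integrator(leapfrog_program(0.01), system,
                           State(np.array([[0.3, 0, 0]]),
                                 np.array([[0.1, 0.2, -0.1]])))
        x_before = integ.ctx.x.copy()
        integ.step(1)
        assert np.array_equal(integ.ctx.v,
                              (integ.ctx.x - x_before) / 0.01)

    def test_custom_velocity_verlet_matches_leapfrog_positions(self):
        dt = 0.002
        params = NonbondedParams([0.0, 0.0], [0.34, 0.34], [1.0, 1.0])
        term = NonbondedTerm(params)
        pos = np.array([[0.0, 0, 0], [0.42, 0, 0]])
        v0 = np.array([[0.05, 0, 0], [-0.05, 0, 0]])
        vv = IntegratorProgram(step_size=dt)
        vv.add_compute_per_dof("v", "v+0.5*dt*f/m")
        vv.add_compute_per_dof("x", "x+dt*v")
        vv.add_compute_per_dof("v", "v+0.5*dt*f/m")
        sys_a = System(np.array([39.948, 39.948]), force_terms=[term])
        _, f0 = term.energy_and_forces(pos)
        v_half = v0 - 0.5 * dt * f0 / sys_a.masses[:, None]
        ivv = Integrator(vv, sys_a, State(pos.copy(), v0.copy()))
        ilf = Integrator(leapfrog_program(dt), sys_a, State(pos.copy(), v_half))
        ivv.step(100)
        ilf.step(100)
        assert np.abs(ivv.ctx.x - ilf.ctx.x).max() < 1e-10


class TestLangevin:
    def test_zero_friction_reduces_to_kick_drift(self):
        system = System(np.array([1.0]), force_terms=[ConstantForce()])
        lg = Integrator(langevin_program(300.0, 0.0, 1.0), system,
                        State(np.zeros((1, 3))))
        lf = Integrator(leapfrog_program(1.0), system, State(np.zeros((1, 3))))
        lg.step(3)
        lf.step(3)
        assert np.array_equal(lg.ctx.x, lf.ctx.x)
        assert np.array_equal(lg.ctx.v, lf.ctx.v)

    def test_equipartition_of_free_particles(self):
        # 12 free particles x 3 components x ~28k steps: ~1e6 velocity
        # samples; the stationary variance must be kB T / m within 3%
        n = 12
        system = System(np.full(n, 1.0), force_terms=[ZeroForce()])
        integ = Integrator(langevin_program(300.0, 2.0, 0.05), system,
                           State(np.zeros((n, 3))), seed=7)
        integ.step(2000)  # decorrelate from the cold start
        acc = 0.0
        count = 0
        for _ in range(28000):
            integ.step(1)
            acc += float(np.sum(integ.ctx.v**2))
            count += 3 * n
        var = acc / count
        assert var == pytest.approx(KB * 300.0, rel=0.03)

    def test_same_seed_gives_bit_identical_trajectory(self):
        system = System(np.array([1.0, 4.0]), force_terms=[ZeroForce()])
        runs = []
        for _ in range(2):
            integ = Integrator(langevin_program(300.0, 1.0, 0.002), system,
                               State(np.zeros((2, 3))), seed=99)
            integ.step(50)
            runs.append((integ.ctx.x.copy(), integ.ctx.v.copy()))
        assert np.array_equal(runs[0][0], runs[1][0])
        assert np.array_equal(runs[0][1], runs[1][1])

    def test_different_seeds_differ(self):
        system = System(np.array([1.0]), force_terms=[ZeroForce()])
        a = Integrator(langevin_program(300.0, 1.0, 0.002), system,
                       State(np.zeros((1, 3))), seed=1)
        b = Integrator(langevin_program(300.0, 1.0, 0.002), system,
                       State(np.zeros((1, 3))), seed=2)
        a.step(10)
        b.step(10)
        assert not np.array_equal(a.ctx.v, b.ctx.v)


class TestShake:
    def test_equal_mass_diatomic_moves_symmetrically(self):
        x_ref = np.array([[0.0, 0, 0], [0.0, 0, 1.2]])
        out = shake_positions([ConstraintDef(0, 1, 1.0)], x_ref, x_ref.copy(),
                              np.array([1.0, 1.0]))
        assert np.allclose(out, [[0, 0, 0.1], [0, 0, 1.1]], atol=1e-7)

    def test_immobile_partner_stays_fixed(self):
        x_ref = np.array([[0.0, 0, 0], [0.0, 0, 1.3]])
        out = shake_positions([ConstraintDef(0, 1, 1.0)], x_ref, x_ref.copy(),
                              np.array([0.0, 1.0]))  # zero inverse mass
        assert np.allclose(out[0], [0, 0, 0])
        assert np.linalg.norm(out[1] - out[0]) == pytest.approx(1.0, abs=1e-8)

    def test_rigid_water_triangle_converges_from_random_kicks(self, rng):
        r_oh, r_hh = 0.09572, 0.15139
        base = np.array([[0.0, 0, 0],
                         [r_oh, 0, 0],
                         [r_oh * np.cos(1.824), r_oh * np.sin(1.824), 0]])
        cons = [ConstraintDef(0, 1, r_oh), ConstraintDef(0, 2, r_oh),
                ConstraintDef(1, 2, r_hh)]
        inv_m = 1.0 / np.array([15.999, 1.008, 1.008])
        for _ in range(1000):
            kicked = base + rng.uniform(-0.02, 0.02, size=(3, 3))
            out = shake_positions(cons, base, kicked, inv_m, tol=1e-8)
            for c in cons:
                d = np.linalg.norm(out[c.i] - out[c.j])
                assert abs(d - c.distance) / c.distance <= 1e-8


class TestRattle:
    def test_opposed_radial_velocities_are_zeroed(self):
        x = np.array([[0.0, 0, 0], [0.0, 0, 1.0]])
        v = np.array([[0.0, 0, 0.5], [0.0, 0, -0.5]])
        out = rattle_velocities([ConstraintDef(0, 1, 1.0)], x, v,
                                np.array([1.0, 1.0]))
        assert np.allclose(out, 0, atol=1e-12)

    def test_tangential_velocities_untouched(self):
        x = np.array([[0.0, 0, 0], [0.0, 0, 1.0]])
        v = np.array([[0.3, -0.2, 0], [0.1, 0.4, 0]])
        out = rattle_velocities([ConstraintDef(0, 1, 1.0)], x, v,
                                np.array([1.0, 1.0]))
        assert np.allclose(out, v, atol=1e-12)

    def test_projection_never_increases_kinetic_energy(self, rng):
        for _ in range(50):
            x = rng.normal(size=(4, 3))
            cons = [ConstraintDef(0, 1, float(np.linalg.norm(x[0] - x[1]))),
                    ConstraintDef(2, 3, float(np.linalg.norm(x[2] - x[3]))),
                    ConstraintDef(1, 2, float(np.linalg.norm(x[1] - x[2])))]
            m = rng.uniform(1, 16, 4)
            v = rng.normal(size=(4, 3))
            out = rattle_velocities(cons, x, v, 1.0 / m)
            for c in cons:
                rhat = (x[c.i] - x[c.j])
                rhat = rhat / np.linalg.norm(rhat)
                assert abs((out[c.i] - out[c.j]) @ rhat) <= 1e-8
            ke_before = 0.5 * np.sum(m[:, None] * v**2)
            ke_after = 0.5 * np.sum(m[:, None] * out**2)
            assert ke_after <= ke_before + 1e-12
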