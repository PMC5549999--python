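"""Programmable integrator DSL plus SHAKE/RATTLE constraint solvers.

A time step is an ordered program of operations: per-degree-of-freedom
computations (``v = v + dt*f/m``), global computations, sums over degrees of
freedom, constraint applications, and if/while flow control.  The built-in
leapfrog Verlet and Langevin integrators are expressed in the same DSL, so
one execution engine covers everything.

Semantics
---------
Per-DOF expressions are evaluated componentwise over the 3N Cartesian
components of the massive particles; ``x``, ``v``, ``f`` expose the matching
component, ``m`` broadcasts per particle, ``dt`` is the step size.  Virtual
sites (massless) are never integrated: per-DOF assignments skip them, their
positions are rebuilt from their parents before every force evaluation, and
sums run over massive particles only (equivalently, their mass acts as
infinite so ``f/m`` vanishes).  ``gaussian`` and ``uniform`` draw fresh
i.i.d. values per component per evaluation from a counter-based generator
keyed by (seed, step index, evaluation counter), which makes trajectories
bit-reproducible for a fixed seed.  Any operation that writes ``x``
invalidates the cached forces; ``f`` is recomputed lazily (with virtual
sites repositioned) before its next read.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import expr as _expr
from .system import KB, State, System
from .vsites import apply_site_forces, update_all_sites

__all__ = [
    "StepOp",
    "IntegratorProgram",
    "Integrator",
    "execute_step",
    "leapfrog_program",
    "langevin_program",
    "shake_positions",
    "rattle_velocities",
]

_BUILTINS = {"x", "v", "f", "m", "dt", "gaussian", "uniform"}
_COMPARATORS = {
    "<": np.less, "<=": np.less_equal, ">": np.greater,
    ">=": np.greater_equal, "=": np.equal, "!=": np.not_equal,
}
WHILE_ITERATION_CAP = 1000


@dataclass
class StepOp:
    """One operation of an integrator program."""

    kind: str  # compute_per_dof | compute_global | compute_sum |
               # constrain_positions | constrain_velocities | if_block | while_block
    target: str = ""
    expression: object = None          # str or ParsedExpression
    condition: tuple | None = None     # (lhs, comparator, rhs)
    body: list = field(default_factory=list)


@dataclass
class IntegratorProgram:
    """Ordered computation steps defining one time step of dynamics."""

    step_size: float
    per_dof_variables: dict = field(default_factory=dict)
    global_variables: dict = field(default_factory=dict)
    steps: list = field(default_factory=list)

    def __post_init__(self):
        names = set(self.per_dof_variables) | set(self.global_variables)
        if len(names) != len(self.per_dof_variables) + len(self.global_variables):
            raise ValueError("variable names must be unique across scopes")
        clash = names & _BUILTINS
        if clash:
            raise ValueError(f"variable names shadow builtins: {sorted(clash)}")
        _check_nesting(self.steps)

    def add_per_dof_variable(self, name, initial=0.0):
        if name in _BUILTINS or name in self.global_variables \
                or name in self.per_dof_variables:
            raise ValueError(f"variable name {name!r} unavailable")
        self.per_dof_variables[name] = initial

    def add_global_variable(self, name, initial=0.0):
        if name in _BUILTINS or name in self.global_variables \
                or name in self.per_dof_variables:
            raise ValueError(f"variable name {name!r} unavailable")
        self.global_variables[name] = initial

    def add_compute_per_dof(self, target, expression):
        self.steps.append(StepOp("compute_per_dof", target, expression))

    def add_compute_global(self, target, expression):
        self.steps.append(StepOp("compute_global", target, expression))

    def add_compute_sum(self, target, expression):
        self.steps.append(StepOp("compute_sum", target, expression))

    def add_constrain_positions(self):
        self.steps.append(StepOp("constrain_positions"))

    def add_constrain_velocities(self):
        self.steps.append(StepOp("constrain_velocities"))


def _check_nesting(steps, depth=0):
    if depth > 32:
        raise ValueError("if/while nesting too deep")
    for op in steps:
        if op.kind in ("if_block", "while_block"):
            if op.condition is None:
                raise ValueError(f"{op.kind} requires a condition")
            _check_nesting(op.body, depth + 1)


def _as_pe(expression) -> _expr.ParsedExpression:
    if isinstance(expression, _expr.ParsedExpression):
        return expression
    return _expr.parse(expression)


class _ExecContext:
    """Mutable execution state of one integrator attached to a system."""

    def __init__(self, program: IntegratorProgram, system: System, state: State,
                 seed: int, force_fn, round32: bool = False):
        self.program = program
        self.system = system
        self.seed = int(seed)
        self.force_fn = force_fn
        self.round32 = round32  # emulate 32-bit storage of integrated variables
        n = system.n_particles
        self.massive = np.array([system.masses[i] > 0 for i in range(n)])
        self.x = update_all_sites(system, np.array(state.positions, dtype=float))
        self.v = np.array(state.velocities, dtype=float)
        self.m = system.masses[self.massive][:, None]  # (n_massive, 1)
        self.inv_masses = np.where(system.masses > 0, 1.0 / np.where(
            system.masses > 0, system.masses, 1.0), 0.0)
        self.per_dof = {}
        for name, init in program.per_dof_variables.items():
            arr = np.zeros((n, 3))
            arr[:] = init
            self.per_dof[name] = arr
        self.globals = {name: float(v) for name, v in program.global_variables.items()}
        self.step_index = 0
        self._eval_counter = 0
        self.forces = None
        self.potential = None
        self._compiled: dict[int, tuple] = {}

    # -- forces -----------------------------------------------------------

    def get_forces(self):
        if self.forces is None:
            self.x = update_all_sites(self.system, self.x)
            e, f = self.force_fn(self.x)
            f = apply_site_forces(self.system, self.x, f)
            self.potential, self.forces = e, f
        return self.forces

    def invalidate_forces(self):
        self.forces = None

    # -- expression evaluation -------------------------------------------

    def _rng(self):
        rng = np.random.default_rng(
            (0x5EED, self.seed, self.step_index, self._eval_counter))
        self._eval_counter += 1
        return rng

    def _compiled_for(self, op: StepOp, scope: str):
        key = id(op)
        if key not in self._compiled:
            pe = _as_pe(op.expression)
            order = sorted(pe.free_variables)
            self._compiled[key] = (pe, order, _expr.compile_function(pe, order))
        return self._compiled[key]

    def _per_dof_args(self, names, rng):
        sel = self.massive
        nm = int(np.sum(sel))
        args = []
        for name in names:
            if name == "x":
                args.append(self.x[sel])
            elif name == "v":
                args.append(self.v[sel])
            elif name == "f":
                args.append(self.get_forces()[sel])
            elif name == "m":
                args.append(self.m)
            elif name == "dt":
                args.append(self.program.step_size)
            elif name == "gaussian":
                args.append(rng.standard_normal((nm, 3)))
            elif name == "uniform":
                args.append(rng.random((nm, 3)))
            elif name in self.per_dof:
                args.append(self.per_dof[name][sel])
            elif name in self.globals:
                args.append(self.globals[name])
            else:
                raise NameError(f"unbound variable {name!r} in per-DOF expression")
        return args

    def eval_per_dof(self, op: StepOp):
        _, names, fn = self._compiled_for(op, "dof")
        rng = self._rng()
        out = fn(*self._per_dof_args(names, rng))
        sel = self.massive
        result = np.broadcast_to(np.asarray(out, dtype=float),
                                 (int(np.sum(sel)), 3))
        return result

    def eval_global(self, expression):
        pe = _as_pe(expression)
        order = sorted(pe.free_variables)
        fn = _expr.compile_function(pe, order)
        rng = self._rng()
        args = []
        for name in order:
            if name == "dt":
                args.append(self.program.step_size)
            elif name == "gaussian":
                args.append(rng.standard_normal())
            elif name == "uniform":
                args.append(rng.random())
            elif name in self.globals:
                args.append(self.globals[name])
            else:
                raise NameError(f"unbound variable {name!r} in global expression")
        return float(fn(*args))

    # -- operations -------------------------------------------------------

    def run_ops(self, ops):
        for op in ops:
            self.run_op(op)

    def run_op(self, op: StepOp):
        kind = op.kind
        if kind == "compute_per_dof":
            result = self.eval_per_dof(op)
            self.assign_per_dof(op.target, result)
        elif kind == "compute_sum":
            if op.target not in self.globals:
                raise NameError(f"compute_sum target {op.target!r} is not global")
            result = self.eval_per_dof(op)
            self.globals[op.target] = float(np.sum(result))
        elif kind == "compute_global":
            if op.target not in self.globals:
                raise NameError(f"compute_global target {op.target!r} is not global")
            self.globals[op.target] = self.eval_global(op.expression)
        elif kind == "constrain_positions":
            if self.system.constraints:
                self.x = shake_positions(
                    self.system.constraints, self.x_ref, self.x, self.inv_masses)
                self.invalidate_forces()
        elif kind == "constrain_velocities":
            if self.system.constraints:
                self.v = rattle_velocities(
                    self.system.constraints, self.x, self.v, self.inv_masses)
        elif kind == "if_block":
            if self.eval_condition(op.condition):
                self.run_ops(op.body)
        elif kind == "while_block":
            count = 0
            while self.eval_condition(op.condition):
                count += 1
                if count > WHILE_ITERATION_CAP:
                    raise RuntimeError(
                        f"while block exceeded {WHILE_ITERATION_CAP} iterations")
                self.run_ops(op.body)
        else:
            raise ValueError(f"unknown step kind {kind!r}")

    def assign_per_dof(self, target, result):
        sel = self.massive
        if self.round32:
            result = np.asarray(result, dtype=np.float32).astype(np.float64)
        if target == "x":
            self.x[sel] = result
            self.invalidate_forces()
        elif target == "v":
            self.v[sel] = result
        elif target in self.per_dof:
            self.per_dof[target][sel] = result
        else:
            raise NameError(f"compute_per_dof target {target!r} is not per-DOF")

    def eval_condition(self, condition):
        lhs, comparator, rhs = condition
        if comparator not in _COMPARATORS:
            raise ValueError(f"unknown comparator {comparator!r}")
        return bool(_COMPARATORS[comparator](self.eval_global(lhs),
                                             self.eval_global(rhs)))

    def do_step(self):
        self.x_ref = self.x.copy()  # reference geometry for SHAKE directions
        self._eval_counter = 0
        self.run_ops(self.program.steps)
        self.step_index += 1


class Integrator:
    """Persistent executor: caches forces across steps, tracks time."""

    def __init__(self, program: IntegratorProgram, system: System, state: State,
                 seed: int = 0, force_fn=None, round32: bool = False):
        if force_fn is None:
            force_fn = _default_force_fn(system)
        self.ctx = _ExecContext(program, system, state, seed, force_fn, round32)
        self.time = state.time
        self.program = program
        self.system = system

    def step(self, n: int = 1):
        for _ in range(n):
            self.ctx.do_step()
            self.time += self.program.step_size

    def state(self, energies: bool = True) -> State:
        ctx = self.ctx
        st = State(ctx.x.copy(), ctx.v.copy(), time=self.time)
        if energies:
            st.forces = ctx.get_forces().copy()
            st.potential_energy = ctx.potential
            st.kinetic_energy = float(
                0.5 * np.sum(self.system.masses[:, None] * ctx.v**2))
        return st


def _default_force_fn(system: System):
    def fn(positions):
        total_e = 0.0
        total_f = np.zeros_like(positions)
        for term in system.force_terms:
            e, f = term.energy_and_forces(positions, system.box)
            total_e += e
            total_f += f
        return total_e, total_f
    return fn


def execute_step(program: IntegratorProgram, system: System, state: State,
                 rng_seed: int = 0, force_fn=None, step_index: int = 0) -> State:
    """Run one time step of ``program`` and return the new state."""
    integ = Integrator(program, system, state, rng_seed, force_fn)
    integ.ctx.step_index = step_index
    integ.step(1)
    return integ.state()


# ---------------------------------------------------------------------------
# built-in programs
# ---------------------------------------------------------------------------

def leapfrog_program(dt: float) -> IntegratorProgram:
    """Leapfrog Verlet: kick, drift, constrain, recompute v = (x-x0)/dt."""
    prog = IntegratorProgram(step_size=dt)
    prog.add_per_dof_variable("x0", 0.0)
    prog.add_compute_per_dof("x0", "x")
    prog.add_compute_per_dof("v", "v+dt*f/m")
    prog.add_compute_per_dof("x", "x+dt*v")
    prog.add_constrain_positions()
    prog.add_compute_per_dof("v", "(x-x0)/dt")
    return prog


def langevin_program(T: float, gamma: float, dt: float) -> IntegratorProgram:
    """Langevin dynamics via the exponential (BAO-style) discretization.

    Per DOF: v <- a*v + (1-a)*f/(m*gamma) + sqrt(kB*T*(1-a^2)/m)*gaussian
    with a = exp(-gamma*dt), then a position drift and constraint projection.
    gamma = 0 reduces exactly to the deterministic kick-drift update.
    """
    if gamma < 0 or T < 0:
        raise ValueError("gamma and T must be non-negative")
    a = float(np.exp(-gamma * dt))
    b = (1.0 - a) / gamma if gamma > 0 else dt
    kT = KB * T
    prog = IntegratorProgram(step_size=dt)
    prog.add_global_variable("acoef", a)
    prog.add_global_variable("bcoef", b)
    prog.add_global_variable("kT", kT)
    prog.add_per_dof_variable("x0", 0.0)
    prog.add_compute_per_dof("x0", "x")
    prog.add_compute_per_dof(
        "v", "acoef*v + bcoef*f/m + sqrt(kT*(1-acoef*acoef)/m)*gaussian")
    prog.add_compute_per_dof("x", "x+dt*v")
    prog.add_constrain_positions()
    prog.add_compute_per_dof("v", "(x-x0)/dt")
    return prog


# ---------------------------------------------------------------------------
# constraint solvers
# ---------------------------------------------------------------------------

def shake_positions(constraints, x_ref, x_new, inv_masses, tol: float = 1e-8,
                    max_iter: int = 150) -> np.ndarray:
    """Iteratively project ``x_new`` onto the constraint manifold (SHAKE).

    Corrections act along the reference-geometry bond directions, weighted
    by inverse masses (zero inverse mass marks an immobile particle).  On
    return every constraint satisfies ``||xi-xj| - d|/d <= tol``.
    """
    x = np.array(x_new, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    inv_masses = np.asarray(inv_masses, dtype=float)
    cons = [(c.i, c.j, c.distance) for c in constraints]
    for _ in range(max_iter):
        converged = True
        for i, j, d in cons:
            r = x[i] - x[j]
            r2 = float(r @ r)
            diff = r2 - d * d
            if abs(np.sqrt(r2) - d) / d > tol:
                converged = False
                r_ref = x_ref[i] - x_ref[j]
                wsum = inv_masses[i] + inv_masses[j]
                if wsum == 0:
                    raise RuntimeError("constraint between two immobile particles")
                denom = 2.0 * wsum * float(r_ref @ r)
                if abs(denom) < 1e-300:
                    raise RuntimeError("SHAKE reference direction orthogonal to bond")
                g = diff / denom
                x[i] -= g * inv_masses[i] * r_ref
                x[j] += g * inv_masses[j] * r_ref
        if converged:
            return x
    raise RuntimeError(f"SHAKE did not converge within {max_iter} iterations")


def rattle_velocities(constraints, x, v, inv_masses, tol: float = 1e-8,
                      max_iter: int = 150) -> np.ndarray:
    """Remove relative velocity along every constrained bond (RATTLE).

    ``x`` must already satisfy the constraints.  The projection never adds
    kinetic energy.  On return ``|(vi-vj).rhat| <= tol`` for every bond.
    """
    x = np.asarray(x, dtype=float)
    v = np.array(v, dtype=float)
    inv_masses = np.asarray(inv_masses, dtype=float)
    cons = []
    for c in constraints:
        r = x[c.i] - x[c.j]
        rhat = r / np.linalg.norm(r)
        cons.append((c.i, c.j, rhat))
    for _ in range(max_iter):
        converged = True
        for i, j, rhat in cons:
            rv = float((v[i] - v[j]) @ rhat)
            if abs(rv) > tol:
                converged = False
                wsum = inv_masses[i] + inv_masses[j]
                if wsum == 0:
                    raise RuntimeError("constraint between two immobile particles")
                k = rv / wsum
                v[i] -= k * inv_masses[i] * rhat
                v[j] += k * inv_masses[j] * rhat
        if converged:
            return v
    raise RuntimeError(f"RATTLE did not converge within {max_iter} iterations")
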