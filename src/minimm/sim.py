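"""Simulation orchestration: precision modes, fixed-point force accumulation,
minimization, reporters, trajectory output, and the drift-rate estimator.

Precision modes mirror the usual GPU trade-offs on CPU hardware: ``single``
rounds the inputs and every term's outputs to 32-bit floats and accumulates
in 32-bit; ``mixed`` computes term forces in (emulated) 32-bit but
accumulates and integrates in 64-bit; ``double`` is all 64-bit.  Independent
of the mode, forces can be accumulated as 64-bit fixed point integers
(2^32 counts per kJ/mol/nm), which makes the sum exactly associative and
therefore bit-reproducible under any summation order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .integrate import Integrator, IntegratorProgram, shake_positions
from .system import State, System, temperature
from .vsites import apply_site_forces, update_all_sites

__all__ = [
    "FixedPointAccumulator",
    "compute_forces",
    "minimize",
    "run",
    "drift_rate",
    "energy_decomposition",
    "force_projection",
    "StateDataReporter",
    "DCDReporter",
]

PRECISION_MODES = ("single", "mixed", "double")


class FixedPointAccumulator:
    """Deterministic force accumulator: 64-bit integers, 2^32 counts per
    kJ/mol/nm.  Integer addition is exactly associative and commutative, so
    the total is independent of summation order; quantization error is at
    most 2^-33 per contribution."""

    SCALE = float(2**32)
    LIMIT = 2**62  # headroom before declaring overflow

    def __init__(self, shape):
        self.counts = np.zeros(shape, dtype=np.int64)

    def add(self, forces):
        scaled = np.asarray(forces, dtype=float) * self.SCALE
        if np.any(np.abs(scaled) >= self.LIMIT):
            raise OverflowError("force contribution overflows fixed-point range")
        self.counts += np.rint(scaled).astype(np.int64)
        if np.any(np.abs(self.counts) >= self.LIMIT):
            raise OverflowError("fixed-point force accumulator overflow")

    def to_floats(self) -> np.ndarray:
        return self.counts / self.SCALE


def _round32(arr):
    return np.asarray(arr, dtype=np.float32).astype(np.float64)


def compute_forces(system: System, positions, mode: str = "double",
                   fixed_point: bool = False):
    """Total potential energy and forces under the given precision mode.

    Virtual sites are repositioned first and their accumulated forces are
    redistributed to parents at the end.  With ``fixed_point`` each term's
    contribution is quantized into the integer accumulator before summation.
    """
    if mode not in PRECISION_MODES:
        raise ValueError(f"unknown precision mode {mode!r}")
    pos = update_all_sites(system, np.asarray(positions, dtype=float))
    energy, forces = _raw_terms(system, pos, mode, fixed_point)
    forces = apply_site_forces(system, pos, forces)
    return energy, forces


def _force_fn(system, mode, fixed_point=False):
    def fn(positions):
        # the Integrator handles virtual-site bookkeeping itself
        e, f = _raw_terms(system, positions, mode, fixed_point)
        return e, f
    return fn


def _raw_terms(system, positions, mode, fixed_point):
    term_pos = _round32(positions) if mode in ("single", "mixed") else positions
    acc = FixedPointAccumulator(positions.shape) if fixed_point else None
    total_f = np.zeros(positions.shape,
                       dtype=np.float32 if mode == "single" else np.float64)
    energy = np.float32(0.0) if mode == "single" else 0.0
    for term in system.force_terms:
        e, f = term.energy_and_forces(term_pos, system.box)
        if mode in ("single", "mixed"):
            f = _round32(f)
            e = float(np.float32(e))
        if acc is not None:
            acc.add(f)
        else:
            total_f = total_f + f.astype(total_f.dtype)
        energy = np.float32(energy + np.float32(e)) if mode == "single" else energy + e
    forces = acc.to_floats() if acc is not None else np.asarray(total_f, dtype=float)
    return float(energy), forces


# ---------------------------------------------------------------------------
# minimization
# ---------------------------------------------------------------------------

def minimize(system: System, state: State, force_tolerance: float = 10.0,
             max_iterations: int = 1000) -> State:
    """Local energy minimization (L-BFGS) with constraint re-projection.

    Optimizes the coordinates of massive particles (virtual sites are
    recomputed inside the objective); stops when the largest per-component
    force is below ``force_tolerance`` (kJ/mol/nm) or the iteration cap is
    reached.  Constraints are re-satisfied at exit with SHAKE.
    """
    pos0 = update_all_sites(system, np.asarray(state.positions, dtype=float))
    massive = system.masses > 0
    idx = np.nonzero(massive)[0]

    def assemble(xflat):
        p = pos0.copy()
        p[idx] = xflat.reshape(-1, 3)
        return update_all_sites(system, p)

    def objective(xflat):
        p = assemble(xflat)
        e, f = compute_forces(system, p, mode="double")
        if not np.isfinite(e):
            raise FloatingPointError("non-finite energy during minimization")
        return e, -f[idx].reshape(-1)

    x0 = pos0[idx].reshape(-1)
    result = optimize.minimize(
        objective, x0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iterations, "gtol": force_tolerance / 10.0,
                 "ftol": 1e-14},
    )
    pos = assemble(result.x)
    if system.constraints:
        inv_m = np.where(massive, 1.0 / np.where(massive, system.masses, 1.0), 0.0)
        pos = shake_positions(system.constraints, pos0, pos, inv_m)
        pos = update_all_sites(system, pos)
    e, f = compute_forces(system, pos, mode="double")
    out = state.copy()
    out.positions = pos
    out.forces = f
    out.potential_energy = e
    return out


# ---------------------------------------------------------------------------
# reporters
# ---------------------------------------------------------------------------

class StateDataReporter:
    """Append time/energy/temperature rows to a CSV file every ``interval``
    steps."""

    QUANTITIES = ("time", "potential_energy", "kinetic_energy",
                  "total_energy", "temperature")

    def __init__(self, path, interval: int, quantities=None):
        if interval < 1:
            raise ValueError("reporter interval must be >= 1")
        self.interval = interval
        self.quantities = list(quantities or self.QUANTITIES)
        self._fh = open(path, "w", newline="")
        self._writer = csv.writer(self._fh)
        self._writer.writerow(self.quantities)

    def report(self, system: System, state: State):
        row = []
        for qty in self.quantities:
            if qty == "time":
                row.append(f"{state.time:.6f}")
            elif qty == "potential_energy":
                row.append(repr(state.potential_energy))
            elif qty == "kinetic_energy":
                row.append(repr(state.kinetic_energy))
            elif qty == "total_energy":
                row.append(repr(state.potential_energy + state.kinetic_energy))
            elif qty == "temperature":
                row.append(repr(temperature(system, state.kinetic_energy)))
            else:
                raise ValueError(f"unknown quantity {qty!r}")
        self._writer.writerow(row)
        self._fh.flush()

    def close(self):
        self._fh.close()


class DCDReporter:
    """Write trajectory frames in CHARMM/X-PLOR DCD layout (via mdtraj),
    including the unit-cell block when the system is periodic."""

    def __init__(self, path, interval: int):
        if interval < 1:
            raise ValueError("reporter interval must be >= 1")
        from mdtraj.formats import DCDTrajectoryFile
        self.interval = interval
        self._fh = DCDTrajectoryFile(str(path), "w")

    def report(self, system: System, state: State):
        xyz = np.asarray(state.positions, dtype=np.float32) * 10.0  # nm -> A
        if system.box is not None:
            from .amberio import _box_to_lengths_angles
            la, lb, lc, al, be, ga = _box_to_lengths_angles(system.box)
            self._fh.write(xyz, cell_lengths=np.array([[la, lb, lc]]),
                           cell_angles=np.array([[al, be, ga]]))
        else:
            self._fh.write(xyz)

    def close(self):
        self._fh.close()


# ---------------------------------------------------------------------------
# running dynamics
# ---------------------------------------------------------------------------

def run(system: System, program: IntegratorProgram, state: State,
        n_steps: int, reporters=(), mode: str = "double", seed: int = 0,
        fixed_point: bool = False) -> State:
    """Advance ``n_steps`` of dynamics, firing reporters at their intervals."""
    if mode not in PRECISION_MODES:
        raise ValueError(f"unknown precision mode {mode!r}")
    integ = Integrator(program, system, state, seed=seed,
                       force_fn=_force_fn(system, mode, fixed_point),
                       round32=(mode == "single"))
    for step in range(1, n_steps + 1):
        integ.step(1)
        due = [r for r in reporters if step % r.interval == 0]
        if due:
            snap = integ.state(energies=True)
            for r in due:
                r.report(system, snap)
    return integ.state(energies=True)


# ---------------------------------------------------------------------------
# analysis
# ---------------------------------------------------------------------------

def drift_rate(times, total_energies):
    """OLS slope of total energy versus time: (rate, standard error).

    This is the standard way to quantify energy drift in nominally
    energy-conserving dynamics.
    """
    times = np.asarray(times, dtype=float)
    energies = np.asarray(total_energies, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples for a drift estimate")
    res = stats.linregress(times, energies)
    return float(res.slope), float(res.stderr)


def energy_decomposition(system: System, state: State) -> dict:
    """Per-category potential energies (Bond/Angle/Dihedral/Nonbonded/OBC)
    plus their Total, in kJ/mol."""
    pos = update_all_sites(system, np.asarray(state.positions, dtype=float))
    out: dict[str, float] = {}
    for term in system.force_terms:
        e, _ = term.energy_and_forces(pos, system.box)
        cat = getattr(term, "category", "Other")
        out[cat] = out.get(cat, 0.0) + e
    out["Total"] = sum(out.values())
    return out


def force_projection(f_ref, f_test):
    """Per-atom normalized projection (f_ref . f_test)/(f_test . f_test);
    returns (mean, min, max) over atoms — 1.0 everywhere means agreement."""
    f_ref = np.asarray(f_ref, dtype=float)
    f_test = np.asarray(f_test, dtype=float)
    if f_ref.shape != f_test.shape:
        raise ValueError("force arrays must have matching shapes")
    denom = np.einsum("nd,nd->n", f_test, f_test)
    if np.any(denom == 0):
        raise ValueError("zero-norm test force on at least one atom")
    proj = np.einsum("nd,nd->n", f_ref, f_test) / denom
    return float(proj.mean()), float(proj.min()), float(proj.max())
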