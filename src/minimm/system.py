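"""Molecular system model: particles, constraints, force terms, virtual sites.

Internal units throughout the engine: nm, ps, amu, kJ/mol, elementary charge
and kelvin.  With these, kB = 0.00831446... kJ/mol/K and masses in amu make
(1/2) m v^2 come out directly in kJ/mol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KB",
    "COULOMB_CONSTANT",
    "System",
    "State",
    "ConstraintDef",
    "kinetic_energy",
    "set_velocities_to_temperature",
    "repartition_hydrogen_mass",
]

#: Boltzmann constant in kJ/mol/K (CODATA, via R = N_A * kB)
KB = 8.31446261815324e-3

#: Coulomb prefactor 1/(4 pi eps0) in kJ*nm/(mol*e^2)
COULOMB_CONSTANT = 138.935456


@dataclass
class ConstraintDef:
    """Fixed-distance constraint between particles ``i`` and ``j`` (nm)."""

    i: int
    j: int
    distance: float

    def __post_init__(self):
        if self.distance <= 0:
            raise ValueError("constraint distance must be positive")
        if self.i == self.j:
            raise ValueError("constraint endpoints must be distinct")


@dataclass
class System:
    """Particles, masses (amu; 0 marks a virtual site), constraints, force
    terms, virtual sites and an optional periodic box."""

    masses: np.ndarray
    constraints: list[ConstraintDef] = field(default_factory=list)
    force_terms: list = field(default_factory=list)
    virtual_sites: dict = field(default_factory=dict)
    box: object | None = None
    molecule_groups: list | None = None

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)

    @property
    def n_particles(self) -> int:
        return len(self.masses)

    def is_virtual(self, i: int) -> bool:
        return i in self.virtual_sites

    def validate(self):
        n = self.n_particles
        if np.any(self.masses < 0):
            raise ValueError("negative mass")
        for i in range(n):
            if self.masses[i] == 0 and not self.is_virtual(i):
                raise ValueError(f"particle {i} has zero mass but is not a virtual site")
            if self.masses[i] != 0 and self.is_virtual(i):
                raise ValueError(f"virtual site {i} must have zero mass")
        seen = set()
        for c in self.constraints:
            if not (0 <= c.i < n and 0 <= c.j < n):
                raise ValueError("constraint index out of range")
            if self.is_virtual(c.i) or self.is_virtual(c.j):
                raise ValueError("constraints may not touch virtual sites")
            key = (min(c.i, c.j), max(c.i, c.j))
            if key in seen:
                raise ValueError(f"duplicate constraint on pair {key}")
            seen.add(key)

    def degrees_of_freedom(self) -> int:
        """3*(non-virtual particles) - constraints - 3 (center of mass)."""
        n_real = self.n_particles - len(self.virtual_sites)
        return 3 * n_real - len(self.constraints) - 3


@dataclass
class State:
    """Instantaneous simulation state."""

    positions: np.ndarray
    velocities: np.ndarray | None = None
    forces: np.ndarray | None = None
    time: float = 0.0
    potential_energy: float = 0.0
    kinetic_energy: float = 0.0

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.velocities is None:
            self.velocities = np.zeros_like(self.positions)
        else:
            self.velocities = np.asarray(self.velocities, dtype=float)
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
        if self.velocities.shape != self.positions.shape:
            raise ValueError("velocities shape must match positions")

    def copy(self) -> "State":
        return State(
            self.positions.copy(),
            self.velocities.copy(),
            None if self.forces is None else self.forces.copy(),
            self.time,
            self.potential_energy,
            self.kinetic_energy,
        )


def kinetic_energy(system: System, state: State) -> float:
    """Sum of (1/2) m v^2 over non-virtual particles, in kJ/mol."""
    m = system.masses
    v2 = np.sum(state.velocities**2, axis=1)
    return float(0.5 * np.sum(m * v2))


def temperature(system: System, ke: float) -> float:
    """Instantaneous temperature from kinetic energy via equipartition."""
    dof = system.degrees_of_freedom()
    return 2.0 * ke / (dof * KB) if dof > 0 else 0.0


def set_velocities_to_temperature(system: System, T: float, seed: int) -> np.ndarray:
    """Maxwell-Boltzmann velocities: per-DOF Gaussian with variance kB*T/m.

    Virtual sites get zero velocity.  Deterministic under a fixed seed.
    """
    if T < 0:
        raise ValueError("temperature must be non-negative")
    rng = np.random.default_rng(seed)
    n = system.n_particles
    v = np.zeros((n, 3))
    if T == 0:
        return v
    raw = rng.standard_normal((n, 3))
    for i in range(n):
        if system.masses[i] > 0:
            v[i] = raw[i] * np.sqrt(KB * T / system.masses[i])
    return v


def repartition_hydrogen_mass(
    system: System,
    bonds: list[tuple[int, int]],
    hydrogen_flags: np.ndarray,
    target_mass: float = 4.0,
) -> System:
    """Shift mass from heavy atoms onto their bonded hydrogens.

    Each hydrogen's mass becomes ``target_mass`` (amu); its unique bonded
    heavy atom loses the difference, keeping the total system mass exactly
    constant.  This permits larger integration steps by slowing the fastest
    (H-stretch) motions.
    """
    hydrogen_flags = np.asarray(hydrogen_flags, dtype=bool)
    masses = system.masses.copy()
    partner: dict[int, int] = {}
    for i, j in bonds:
        for h, heavy in ((i, j), (j, i)):
            if hydrogen_flags[h] and not hydrogen_flags[heavy]:
                if h in partner:
                    raise ValueError(f"hydrogen {h} bonded to more than one heavy atom")
                partner[h] = heavy
    for h in np.nonzero(hydrogen_flags)[0]:
        if int(h) not in partner:
            raise ValueError(f"hydrogen {int(h)} has no bonded heavy atom")
        heavy = partner[int(h)]
        delta = target_mass - masses[h]
        if masses[heavy] - delta <= 0:
            raise ValueError(f"repartitioning would leave atom {heavy} with mass <= 0")
        masses[h] = target_mass
        masses[heavy] -= delta
    return System(
        masses,
        constraints=list(system.constraints),
        force_terms=list(system.force_terms),
        virtual_sites=dict(system.virtual_sites),
        box=system.box,
        molecule_groups=system.molecule_groups,
    )
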