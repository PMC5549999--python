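# minimm

A desk-scale molecular dynamics engine for structural bioinformatics and
molecular modelling, built around extensibility rather than raw speed.  It
is aimed at method developers and students who want to define *new*
interactions and *new* integration algorithms as mathematics, not code:

- **Custom forces.**  An interaction is an algebraic energy expression —
  `CustomAngleTerm("k*(theta-theta0)^2", ...)` — which the engine parses,
  differentiates analytically to obtain the force (F = −∇E), and compiles
  into a vectorized callable.  Bond, angle, torsion, external, nonbonded
  pair, compound-bond and centroid-bond variants are provided, alongside
  the standard Amber functional forms and an OBC1 generalized Born
  implicit-solvent term.
- **Custom integrators.**  A time step is a program of per-degree-of-freedom
  and global computations, sums, and SHAKE/RATTLE constraint projections:
  leapfrog Verlet is literally `v ← v + dt·f/m`, `x ← x + dt·v`,
  constrain, `v ← (x−x0)/dt`, and Langevin dynamics, velocity Verlet or
  Monte Carlo moves are written the same way.
- **Generalized virtual sites.**  Massless sites placed in a local frame
  built from three parent atoms (origin weights summing to 1, axis weights
  to 0), with forces redistributed through the exact transpose Jacobian.
- **Triclinic periodic boxes**, including the rhombic dodecahedron (≈71% of
  the cubic volume at equal image distance) and truncated octahedron, with
  an exact minimum-image routine.
- **Deterministic force accumulation.**  Forces can be summed as 64-bit
  fixed-point integers (2³² counts per kJ/mol/nm), making the total
  bit-identical under any summation order; single/mixed/double precision
  modes reproduce the accuracy trade-offs of reduced-precision hardware.
- **Amber input pipeline.**  prmtop/inpcrd readers with full unit
  conversion, 1-4 exception materialization, optional rigid constraints and
  hydrogen mass repartitioning, plus a minimal PDB reader/writer and DCD
  trajectory output.

Everything is validated against independent oracles: finite differences for
every force term, a naive scalar-loop re-implementation of every functional
form, and brute-force searches for the periodic geometry.

## Worked example

Build a small implicit-solvent topology, then ask for its energy
decomposition (the `fixtures` module writes valid Amber files for demos and
tests; with real prmtop/inpcrd files the steps are identical):

```python
import numpy as np
from minimm import fixtures

spec = fixtures.ToyPrmtopSpec(
    atoms=[("C1", 12.011, 0.3, 0.34, 0.45), ("H1", 1.008, -0.1, 0.25, 0.07),
           ("C2", 12.011, -0.2, 0.34, 0.45), ("O1", 15.999, -0.3, 0.30, 0.7),
           ("H2", 1.008, 0.3, 0.25, 0.07)],
    bonds=[(0, 1, 250000.0, 0.11, True), (0, 2, 200000.0, 0.15, False),
           (2, 3, 280000.0, 0.13, False), (3, 4, 300000.0, 0.10, True)],
    angles=[(1, 0, 2, 350.0, 1.91), (0, 2, 3, 400.0, 2.0), (2, 3, 4, 380.0, 1.85)],
    dihedrals=[(1, 0, 2, 3, 4.2, 2, 3.14159265, False),
               (0, 2, 3, 4, 6.0, 3, 0.0, False)],
    gb_radii=[0.17, 0.13, 0.17, 0.15, 0.13],
    gb_screen=[0.72, 0.85, 0.72, 0.79, 0.85])
fixtures.write_toy_prmtop(spec, "toy.prmtop")
fixtures.write_toy_inpcrd(np.array([[0, 0, 0], [0.11, 0, 0], [-0.05, 0.14, 0],
                                    [-0.05, 0.28, 0.02], [0.03, 0.33, 0.05]]),
                          "toy.inpcrd")
```

```sh
$ minimm energy --prmtop toy.prmtop --inpcrd toy.inpcrd --implicit obc1
Bond                37.19 kJ/mol
Angle              271.05 kJ/mol
Dihedral            13.01 kJ/mol
Nonbonded           29.47 kJ/mol
OBC                -22.46 kJ/mol
Total              328.25 kJ/mol
```

The rows are the per-category potential energies of the molecule in OBC1
implicit solvent — harmonic bond and angle strain, periodic torsions, LJ
plus Coulomb over non-excluded pairs (with scaled 1-4 exceptions), and the
generalized Born solvation energy; Total is their sum, and the categories
are additive to it within 1e-9 kJ/mol.  `minimm run config.yaml` runs
dynamics (leapfrog or Langevin, any precision mode, CSV and DCD reporters),
`minimm drift --log output.csv` estimates the energy-drift rate by linear
regression, and `minimm compare-forces` prints the normalized projection
statistics used to compare force sets.

Running dynamics from the library instead:

```python
from minimm import fixtures, sim
from minimm.integrate import leapfrog_program

system, state = fixtures.make_lj_fluid(100, 2.2, T=120.0, seed=1)
final = sim.run(system, leapfrog_program(0.001), state, 1000, mode="double")
```

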