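# Methods

`minimm` is a desk-scale molecular dynamics engine whose organizing idea is
extensibility: interactions are algebraic energy expressions compiled to
forces by analytic differentiation, and integrators are small programs in a
per-degree-of-freedom DSL.  This note records the models implemented, the
numerical choices made where the design was genuinely open, and what the
synthetic fixtures do and do not demonstrate.

## Units

nm, ps, amu, kJ/mol, elementary charge, kelvin throughout.  In this system
kB = 8.31446261815324e-3 kJ/mol/K and the Coulomb prefactor
1/(4 pi eps0) = 138.935456 kJ nm / (mol e^2).  Amber inputs are converted on
read: kcal/mol x 4.184, Angstrom x 0.1, charges divided by 18.2223.

## Expression engine

Expressions support reals, identifiers, `+ - * / ^` (with `^`
right-associative and binding tighter than unary minus), parentheses,
function calls, and trailing semicolon-separated intermediate definitions
(`"E; sig=0.5*(sig1+sig2); ..."`), which may reference each other
acyclically.  The function table is sin, cos, tan, asin, acos, atan, sinh,
cosh, tanh, exp, log (natural), sqrt, abs, floor, ceil, min, max, step,
delta, select(cond,a,b).  Conventions: `step(x)` is 1 for x >= 0, `delta(x)`
is 1 only at exactly 0, both differentiate to 0 everywhere; `0^0 = 1`;
division by zero, log of a non-positive value, sqrt of a negative and
fractional powers of negatives raise at evaluation time, never at parse
time.  Differentiation inlines intermediate definitions and applies the
chain rule symbolically; `min`/`max` differentiate through a `step` gate and
`abs` to `2*step(x)-1`.  "Compilation" generates Python source over numpy
primitives — a pure, batch-capable callable whose elementwise evaluation is
bit-identical to scalar evaluation; an independent tree-walk interpreter in
the test suite guards the compiler.

## Force terms

Every term maps `(positions, box) -> (E, F)` with `F = -grad E` exactly
(finite-difference checked in the tests at 1e-4 relative with h = 1e-5 nm).
Standard Amber forms: bonds `k (r-r0)^2`, angles `k (theta-theta0)^2`,
torsions `k (1 + cos(n phi - gamma))`; LJ 12-6 with Lorentz-Berthelot
combination plus Coulomb, with exclusions contributing nothing and
exceptions (materialized 1-4 pairs with SCEE/SCNB scaling, defaults 1.2 and
2.0) replacing the default pair interaction entirely.  Pair loops are plain
O(N^2) with optional per-pair cutoff filtering and the minimum-image
convention when periodic — correctness first at desk scale.

The signed dihedral uses the IUPAC convention in (-pi, pi], computed by the
atan2 form on the two bond-plane normals; the analytic gradients of the end
and central atoms were validated against an independent projection-based
construction and against finite differences.  Angle forces are regularized
by clamping sin(theta) >= 1e-8, so configurations at exactly 0 or pi give
large but finite forces.

Custom terms compile the user expression and its derivative with respect to
the geometric variable (r for bonds and nonbonded pairs, theta for angles
and torsions, raw x/y/z for external forces) and broadcast over the item
table.  Per-particle parameters in pair expressions use the `name1`/`name2`
suffix convention so combination rules can be written as intermediate
definitions.  Compound-bond expressions may call `distance(p_i,p_j)`,
`angle(...)`, `dihedral(...)` and use slot coordinates; each unique
geometric call is lifted to an auxiliary variable, the expression is
differentiated with respect to it, and the chain rule runs through the
geometric primitive's analytic gradient.  Centroid-bond terms evaluate the
same machinery on normalized weighted centroids (weights default to masses)
and share each centroid force among group members in proportion to their
normalized weights.

### Implicit solvent (OBC)

Generalized Born energies follow the Onufriev-Bashford-Case formulation:
HCT pairwise descreening integrals over offset radii (dielectric offset
0.009 nm), effective Born radii through the tanh rescaling with the OBC1
coefficients alpha = 0.8, beta = 0, gamma = 2.909125, and the canonical pair
smoothing f = sqrt(r^2 + Bi Bj exp(-r^2 / (4 Bi Bj))), with solute
dielectric 1 and solvent dielectric 78.5 by default.  The optional nonpolar
term is the ACE surface-area approximation (probe 0.14 nm, surface tension
2.25936 kJ/mol/nm^2), off by default.  Forces include the full chain rule
through the Born radii.  An isolated particle's Born radius equals its
offset radius rho = R - 0.009 nm, so the single-particle energy is the Born
self-energy -k_e (1 - 1/eps_w) q^2 / (2 rho); the tests assert exactly this
closed form.

## Virtual sites

The generalized three-parent rule builds a local frame from an affine
origin (weights summing to 1) and two translation-invariant axis vectors
(weights summing to 0), orthonormalizes via dz = dx x dy, and places the
site at a fixed local offset.  Weight-sum conditions are enforced at
construction; |dx| or |dx x dy| below 1e-10 nm is a degenerate-geometry
error.  Forces on the site are redistributed with the exact transpose
Jacobian of the position rule — including the derivatives of the
normalizations and the cross product — which conserves net force
identically (the Jacobians sum to the identity) and net torque to numerical
precision.  Specialized site types (fixed averages, out-of-plane sites) are
degenerate parameterizations of the same rule, not separate code paths.

## Periodic geometry

Boxes are kept in reduced triclinic form (a along x, b in the xy plane,
off-diagonal components at most half the matching diagonal), obtained by
rotating arbitrary right-handed lattice vectors into the canonical frame
and subtracting integer multiples of earlier vectors.  The rhombic
dodecahedron is represented with a square xy base and c = (w/2, w/2,
w/sqrt(2)) — volume w^3/sqrt(2), about 71% of the cube at equal image
distance — and the truncated octahedron with volume 4 sqrt(3)/9 of the
cube; for both, the nearest nonzero lattice point is exactly the requested
image distance.  The scalar minimum-image routine is exact for any reduced
box: a coarse fractional shift gives an upper bound on the minimum norm,
and the triangular structure of the reduced form (a_z = b_z = 0) bounds the
per-axis index ranges that could still beat it.  Ties are broken by the
lexicographically smallest image indices.  The vectorized path used inside
pair loops searches the 27 neighbouring cells, sufficient for the
well-conditioned cells the constructors produce.  Molecule wrapping
translates whole groups so centroids land in the primary cell, preserving
intramolecular geometry exactly.

## Integrator DSL

A time step is an ordered program of per-DOF computations, global
computations, sums over DOFs, position/velocity constraint projections,
and if/while blocks (while capped at 1000 iterations as a non-termination
guard).  Per-DOF expressions evaluate componentwise over the massive
particles' 3N components; `m` broadcasts per particle.  Virtual sites are
never integrated: assignments skip them, sums exclude them (equivalent to
an infinite mass making f/m vanish), and their positions are rebuilt from
parents before every force evaluation.  Writing `x` invalidates cached
forces; `f` is recomputed lazily before its next read, so velocity-Verlet's
second half-kick sees fresh forces without explicit bookkeeping.
`gaussian`/`uniform` draw fresh i.i.d. values per component per evaluation
from a counter-based generator keyed by (seed, step index, evaluation
index), making trajectories bit-reproducible for a fixed seed.

Built-ins: the five-step leapfrog (save x0, kick v by dt f/m, drift x by
dt v, constrain positions, recompute v = (x - x0)/dt — kinetic energy is
reported from this shifted half-step velocity, with no half-step
averaging), and a Langevin program using the exponential discretization
v <- a v + (1-a) f/(m gamma) + sqrt(kB T (1 - a^2)/m) gaussian with
a = exp(-gamma dt), whose gamma -> 0 limit reduces exactly to kick-drift
and whose stationary velocity variance is kB T / m by construction.

Constraints use SHAKE (corrections along reference-geometry directions
weighted by inverse mass; tolerance 1e-8 relative on distances, 150
iterations) and RATTLE for velocities; rigid water is three distance
constraints, with no analytic special case — one solver, simpler
correctness surface.

## Precision modes and fixed-point accumulation

`double` computes everything in 64-bit.  `mixed` rounds every term's forces
and energy to float32 but accumulates and integrates in 64-bit.  `single`
additionally accumulates in 32-bit and rounds the integrated positions and
velocities to float32 each assignment — emulating 32-bit storage of the
integration state, which is the dominant error source the mode represents.
Independent of mode, forces can be accumulated as 64-bit fixed point at
2^32 counts per kJ/mol/nm: integer addition is exactly associative, so the
total is bit-identical under any summation order, with quantization below
2^-33 per contribution and overflow detected.

Energy drift is estimated as the ordinary least-squares slope of total
energy versus time.  The constant-energy benchmark in the acceptance
checks runs the 100-particle LJ fluid fixture (see below) at dt = 0.001 ps,
discards 3 ps of relaxation (the jittered-lattice start otherwise conflates
configurational relaxation with numerical drift, because the half-step
kinetic-energy convention converts a kinetic-energy trend into a spurious
energy slope of order dt/2 times that trend), then regresses over 10 ps
sampled every step.  Under this protocol double precision drifts at a few
1e-4 kJ/mol/ps and the emulated single mode near 1e-1, reproducing the
qualitative single >> double ordering; the magnitudes are specific to this
small fixture and are not comparable to production-scale solvated-protein
numbers.

## Amber input pipeline

The prmtop reader parses the `%FLAG`/`%FORMAT` fixed-width layout
generically and decodes the Amber conventions: index arrays divided by 3,
negative third/fourth dihedral indices marking suppressed 1-4 pairs and
impropers, the excluded-atom list with its 0 placeholder, per-type LJ
sigma/epsilon recovered from the diagonal of the A/B tables, SCEE/SCNB
defaulting to 1.2/2.0 when absent.  1-4 exceptions come from proper
dihedral records, deduplicated.  `h_bonds`/`all_bonds` constraint options
convert the selected bonds to rigid constraints at their equilibrium
lengths and drop their harmonic terms.  Explicit-solvent PME construction
is refused with a clear error — reciprocal-space electrostatics is outside
this engine's scope — so energy decompositions are computed for vacuum or
OBC1 implicit solvent only.  Restart files are read with Amber's velocity
unit (Angstrom per 1/20.455 ps).  The PDB reader/writer covers fixed-width
ATOM/HETATM records and CRYST1, with element inference from the atom-name
prefix when the element column is absent.

Hydrogen mass repartitioning sets each hydrogen's mass to a target (4 amu
by default) and subtracts the difference from its unique bonded heavy atom,
conserving total mass to machine precision and refusing topologies where a
heavy atom would be left non-positive.

## Minimization

Limited-memory BFGS (scipy L-BFGS-B) on the massive particles' coordinates
with the analytic gradient; virtual sites are recomputed inside the
objective so the gradient flows through parent coordinates.  Constraints
are re-projected with SHAKE at exit.  Convergence targets a maximum
per-component force below the requested tolerance.

## Synthetic fixtures and what they show

The fixtures module generates every input the tests need.  The LJ fluid
(argon-like: sigma = 0.34 nm, epsilon = 0.996 kJ/mol, mass 39.948 amu,
defaults N = 100 in a 2.2 nm cube at 120 K — a moderately dense fluid whose
jittered-lattice start guarantees at least 0.8 sigma separation) is used
without a cutoff, summing all minimum-image pairs, so the potential is
effectively continuous for conservation studies.  A flexible 3-site water
box with TIP3P-like charges exercises bonded, nonbonded and constraint
paths together.  The toy prmtop writer emits genuine fixed-width topologies
(one LJ type per atom, H-first bond ordering, GB sections) that the reader
must round-trip.

`reference_energy` is a deliberately naive scalar-loop re-implementation of
every functional form, written directly from the published formulas with no
shared code with the engine (asserted structurally in the tests), with
forces by central finite differences of its own energies — the independent
oracle for the whole pipeline.

These fixtures demonstrate correctness of the implemented mathematics, not
fidelity to any production force field: no real parameterization, no
explicit-solvent electrostatics, system sizes of tens to hundreds of
particles.  Quantities tied to large solvated systems (production drift
magnitudes, timings) are outside what passing tests establish.

## Known limitations

- O(N^2) pair loops; no neighbour lists, no PME/Ewald, no reaction field,
  no dispersion corrections.
- One three-parent virtual-site rule; no sites with four or more parents.
- SHAKE/RATTLE only (no analytic SETTLE); no barostats or box rescaling.
- The single/mixed modes emulate reduced precision by rounding at term and
  assignment boundaries rather than performing every intermediate operation
  in float32; error magnitudes are representative, not bit-faithful to GPU
  arithmetic.
- The energy-decomposition comparison against published cross-validation
  values requires the original topology/coordinate inputs, which must be
  supplied externally (see `data/2koc/` in the test suite).
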