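"""Synthetic systems, toy Amber file writers and an independent reference.

Everything the test suite needs is generated here deterministically from a
seed — no downloads.  :func:`reference_energy` is a deliberately naive,
scalar-loop re-implementation of every in-scope functional form, written
against the formulas directly (no shared code with :mod:`minimm.forces` or
the expression machinery) so it can serve as an independent oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .forces import NonbondedParams, NonbondedTerm, OBCTerm, standard_bonded_terms
from .geometry import TriclinicBox, box_from_geometry
from .system import State, System, set_velocities_to_temperature

__all__ = [
    "make_lj_fluid",
    "make_harmonic_chain",
    "make_diatomic",
    "make_flexible_water_box",
    "ToyPrmtopSpec",
    "write_toy_prmtop",
    "write_toy_inpcrd",
    "reference_energy",
]

# argon-like LJ species used by the fluid fixture
LJ_SIGMA = 0.34       # nm
LJ_EPSILON = 0.996    # kJ/mol
LJ_MASS = 39.948      # amu


def make_lj_fluid(n: int, box_length: float, T: float = 120.0, seed: int = 0):
    """Periodic cubic LJ fluid on a jittered lattice with MB velocities.

    The lattice spacing guarantees a minimum interparticle distance of at
    least 0.8 sigma; no cutoff is used (all minimum-image pairs), which
    keeps the potential effectively continuous for energy-conservation
    studies at these box sizes.
    """
    rng = np.random.default_rng((seed, n))
    per_side = int(np.ceil(n ** (1.0 / 3.0)))
    spacing = box_length / per_side
    max_jitter = (spacing - 0.8 * LJ_SIGMA) / 2.0
    if max_jitter <= 0:
        raise ValueError("density too high to place particles without overlap")
    jitter = min(0.3 * spacing, max_jitter) * 0.9
    sites = []
    for ix in range(per_side):
        for iy in range(per_side):
            for iz in range(per_side):
                sites.append((ix, iy, iz))
    sites = np.array(sites[:n], dtype=float)
    pos = (sites + 0.5) * spacing + rng.uniform(-jitter, jitter, size=(n, 3))
    box = box_from_geometry("cube", box_length)
    params = NonbondedParams(
        np.zeros(n), np.full(n, LJ_SIGMA), np.full(n, LJ_EPSILON))
    system = System(
        np.full(n, LJ_MASS),
        force_terms=[NonbondedTerm(params, cutoff=None, periodic=True)],
        box=box,
        molecule_groups=[[i] for i in range(n)],
    )
    vel = set_velocities_to_temperature(system, T, seed=int(rng.integers(2**31)))
    return system, State(pos, vel)


def make_harmonic_chain(n: int, k: float = 1000.0, r0: float = 0.15,
                        mass: float = 12.0, seed: int = 0):
    """Linear chain of harmonic bonds, slightly perturbed from equilibrium."""
    rng = np.random.default_rng((seed, n, 7))
    pos = np.zeros((n, 3))
    pos[:, 0] = np.arange(n) * r0
    pos += rng.normal(scale=0.01, size=(n, 3))
    bonds = [(i, i + 1, k, r0) for i in range(n - 1)]
    terms = standard_bonded_terms(bonds, [], [])
    system = System(np.full(n, mass), force_terms=[terms[0]])
    return system, State(pos)


def make_diatomic(k: float = 20000.0, r0: float = 0.12, m1: float = 12.0,
                  m2: float = 16.0, r_init: float | None = None):
    """Two atoms with one harmonic bond along z."""
    r = r0 if r_init is None else r_init
    pos = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, r]])
    terms = standard_bonded_terms([(0, 1, k, r0)], [], [])
    system = System(np.array([m1, m2]), force_terms=[terms[0]])
    return system, State(pos)


def make_flexible_water_box(n_waters: int, box_length: float, T: float = 300.0,
                            seed: int = 0):
    """3-site flexible water: harmonic OH bonds and HOH angle, TIP3P-like
    charges and oxygen LJ.  Exercises both constraint and flexible paths."""
    rng = np.random.default_rng((seed, n_waters, 13))
    r_oh = 0.09572
    theta0 = math.radians(104.52)
    per_side = int(np.ceil(n_waters ** (1.0 / 3.0)))
    spacing = box_length / per_side
    positions = []
    for w in range(n_waters):
        ix, iy, iz = (w % per_side, (w // per_side) % per_side,
                      w // per_side**2)
        o = (np.array([ix, iy, iz]) + 0.5) * spacing \
            + rng.uniform(-0.02, 0.02, size=3)
        h1 = o + np.array([r_oh, 0.0, 0.0])
        h2 = o + r_oh * np.array([math.cos(theta0), math.sin(theta0), 0.0])
        positions += [o, h1, h2]
    n = 3 * n_waters
    masses = np.tile([15.9994, 1.008, 1.008], n_waters).astype(float)
    charges = np.tile([-0.834, 0.417, 0.417], n_waters).astype(float)
    sigma = np.tile([0.315061, 0.1, 0.1], n_waters).astype(float)
    eps = np.tile([0.6364, 0.0, 0.0], n_waters).astype(float)
    bonds, angles, exclusions = [], [], []
    for w in range(n_waters):
        o, h1, h2 = 3 * w, 3 * w + 1, 3 * w + 2
        bonds += [(o, h1, 200000.0, r_oh), (o, h2, 200000.0, r_oh)]
        angles += [(h1, o, h2, 400.0, theta0)]
        exclusions += [(o, h1), (o, h2), (h1, h2)]
    params = NonbondedParams(charges, sigma, eps, exclusions=exclusions)
    terms = standard_bonded_terms(bonds, angles, [])[:2] \
        + [NonbondedTerm(params, cutoff=None, periodic=True)]
    system = System(
        masses, force_terms=terms, box=box_from_geometry("cube", box_length),
        molecule_groups=[[3 * w, 3 * w + 1, 3 * w + 2] for w in range(n_waters)],
    )
    vel = set_velocities_to_temperature(system, T, seed=int(rng.integers(2**31)))
    return system, State(np.array(positions), vel)


# ---------------------------------------------------------------------------
# toy prmtop / inpcrd writers
# ---------------------------------------------------------------------------

@dataclass
class ToyPrmtopSpec:
    """Programmatic description of a small Amber topology.

    ``atoms``: (name, mass amu, charge e, sigma nm, epsilon kJ/mol).
    ``bonds``: (i, j, k kJ/mol/nm^2, r0 nm, involves_hydrogen).
    ``angles``: (i, j, k_atom, k kJ/mol/rad^2, theta0 rad).
    ``dihedrals``: (i, j, k, l, k kJ/mol, periodicity, phase rad, improper).
    ``gb_radii``/``gb_screen``: per-atom, nm / dimensionless (optional).
    """

    atoms: list
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    dihedrals: list = field(default_factory=list)
    gb_radii: list | None = None
    gb_screen: list | None = None
    scee: float = 1.2
    scnb: float = 2.0


def _fmt_section(fh, flag, fmt, values, per_line, render):
    fh.write(f"%FLAG {flag}\n%FORMAT({fmt})\n")
    if not values:
        fh.write("\n")
        return
    for start in range(0, len(values), per_line):
        fh.write("".join(render(v) for v in values[start:start + per_line]) + "\n")


def write_toy_prmtop(spec: ToyPrmtopSpec, path):
    """Emit a syntactically valid prmtop that :func:`read_prmtop` round-trips.

    Each atom gets its own LJ type; A/B tables are built from the per-atom
    sigma/epsilon with Lorentz-Berthelot combination in Amber units.
    """
    natom = len(spec.atoms)
    bonds_h = [b for b in spec.bonds if b[4]]
    bonds_a = [b for b in spec.bonds if not b[4]]
    # one parameter entry per bond/angle/dihedral keeps the writer trivial;
    # type order must match the H-first order the index sections use
    bond_types = [(b[2] / 4.184 / 100.0, b[3] / 0.1) for b in bonds_h + bonds_a]
    angle_types = [(a[3] / 4.184, a[4]) for a in spec.angles]
    dih_types = [(d[4] / 4.184, float(d[5]), d[6]) for d in spec.dihedrals]

    exclusions: dict[int, set] = {i: set() for i in range(natom)}

    def exclude(i, j):
        lo, hi = min(i, j), max(i, j)
        exclusions[lo].add(hi)

    for b in spec.bonds:
        exclude(b[0], b[1])
    for a in spec.angles:
        exclude(a[0], a[2])
        exclude(a[0], a[1])
        exclude(a[1], a[2])
    for d in spec.dihedrals:
        if not d[7]:
            exclude(d[0], d[3])
    excl_counts, excl_list = [], []
    for i in range(natom):
        row = sorted(exclusions[i])
        if row:
            excl_counts.append(len(row))
            excl_list.extend(j + 1 for j in row)
        else:
            excl_counts.append(1)
            excl_list.append(0)

    ntypes = natom
    nb_index = []
    pair_of = {}
    acoef, bcoef = [], []
    for i in range(ntypes):
        for j in range(ntypes):
            lo, hi = min(i, j), max(i, j)
            if (lo, hi) not in pair_of:
                sig = 0.5 * (spec.atoms[lo][3] + spec.atoms[hi][3]) / 0.1  # A
                eps = math.sqrt(spec.atoms[lo][4] * spec.atoms[hi][4]) / 4.184
                acoef.append(4.0 * eps * sig**12)
                bcoef.append(4.0 * eps * sig**6)
                pair_of[(lo, hi)] = len(acoef)
    for i in range(ntypes):
        for j in range(ntypes):
            lo, hi = min(i, j), max(i, j)
            nb_index.append(pair_of[(lo, hi)])

    pointers = [0] * 31
    pointers[0] = natom
    pointers[1] = ntypes
    pointers[2] = len(bonds_h)
    pointers[3] = len(bonds_a)
    pointers[4] = 0          # angles-with-H all written as "without" below
    pointers[5] = len(spec.angles)
    pointers[6] = 0
    pointers[7] = len(spec.dihedrals)
    pointers[10] = len(excl_list)
    pointers[11] = 1
    pointers[12] = len(bonds_a)
    pointers[13] = len(spec.angles)
    pointers[14] = len(spec.dihedrals)
    pointers[15] = len(bond_types)
    pointers[16] = len(angle_types)
    pointers[17] = len(dih_types)
    pointers[18] = ntypes

    def bond_codes(bond_list, type_offset):
        out = []
        for t, b in enumerate(bond_list):
            out += [3 * b[0], 3 * b[1], type_offset + t + 1]
        return out

    with open(path, "w") as fh:
        fh.write("%VERSION  VERSION_STAMP = V0001.000  DATE = 01/01/00  00:00:00\n")
        I = lambda v: f"{int(v):8d}"
        E = lambda v: f"{float(v):16.8E}"
        A4 = lambda v: f"{str(v):<4.4s}"
        _fmt_section(fh, "TITLE", "20a4", ["toy"], 20, A4)
        _fmt_section(fh, "POINTERS", "10I8", pointers, 10, I)
        _fmt_section(fh, "ATOM_NAME", "20a4", [a[0] for a in spec.atoms], 20, A4)
        _fmt_section(fh, "CHARGE", "5E16.8",
                     [a[2] * 18.2223 for a in spec.atoms], 5, E)
        _fmt_section(fh, "MASS", "5E16.8", [a[1] for a in spec.atoms], 5, E)
        _fmt_section(fh, "ATOM_TYPE_INDEX", "10I8",
                     list(range(1, natom + 1)), 10, I)
        _fmt_section(fh, "NUMBER_EXCLUDED_ATOMS", "10I8", excl_counts, 10, I)
        _fmt_section(fh, "NONBONDED_PARM_INDEX", "10I8", nb_index, 10, I)
        _fmt_section(fh, "RESIDUE_LABEL", "20a4", ["MOL"], 20, A4)
        _fmt_section(fh, "RESIDUE_POINTER", "10I8", [1], 10, I)
        _fmt_section(fh, "BOND_FORCE_CONSTANT", "5E16.8",
                     [t[0] for t in bond_types], 5, E)
        _fmt_section(fh, "BOND_EQUIL_VALUE", "5E16.8",
                     [t[1] for t in bond_types], 5, E)
        _fmt_section(fh, "ANGLE_FORCE_CONSTANT", "5E16.8",
                     [t[0] for t in angle_types], 5, E)
        _fmt_section(fh, "ANGLE_EQUIL_VALUE", "5E16.8",
                     [t[1] for t in angle_types], 5, E)
        _fmt_section(fh, "DIHEDRAL_FORCE_CONSTANT", "5E16.8",
                     [t[0] for t in dih_types], 5, E)
        _fmt_section(fh, "DIHEDRAL_PERIODICITY", "5E16.8",
                     [t[1] for t in dih_types], 5, E)
        _fmt_section(fh, "DIHEDRAL_PHASE", "5E16.8",
                     [t[2] for t in dih_types], 5, E)
        _fmt_section(fh, "SCEE_SCALE_FACTOR", "5E16.8",
                     [spec.scee] * len(dih_types), 5, E)
        _fmt_section(fh, "SCNB_SCALE_FACTOR", "5E16.8",
                     [spec.scnb] * len(dih_types), 5, E)
        _fmt_section(fh, "LENNARD_JONES_ACOEF", "5E16.8", acoef, 5, E)
        _fmt_section(fh, "LENNARD_JONES_BCOEF", "5E16.8", bcoef, 5, E)
        _fmt_section(fh, "BONDS_INC_HYDROGEN", "10I8",
                     bond_codes(bonds_h, 0), 10, I)
        _fmt_section(fh, "BONDS_WITHOUT_HYDROGEN", "10I8",
                     bond_codes(bonds_a, len(bonds_h)), 10, I)
        _fmt_section(fh, "ANGLES_INC_HYDROGEN", "10I8", [], 10, I)
        angle_codes = []
        for t, a in enumerate(spec.angles):
            angle_codes += [3 * a[0], 3 * a[1], 3 * a[2], t + 1]
        _fmt_section(fh, "ANGLES_WITHOUT_HYDROGEN", "10I8", angle_codes, 10, I)
        _fmt_section(fh, "DIHEDRALS_INC_HYDROGEN", "10I8", [], 10, I)
        dih_codes = []
        for t, d in enumerate(spec.dihedrals):
            l_code = -3 * d[3] if d[7] else 3 * d[3]
            k_code = 3 * d[2]
            if d[7] and l_code == 0:
                raise ValueError("improper with atom 0 in fourth slot unsupported")
            dih_codes += [3 * d[0], 3 * d[1], k_code, l_code, t + 1]
        _fmt_section(fh, "DIHEDRALS_WITHOUT_HYDROGEN", "10I8", dih_codes, 10, I)
        _fmt_section(fh, "EXCLUDED_ATOMS_LIST", "10I8", excl_list, 10, I)
        if spec.gb_radii is not None:
            _fmt_section(fh, "RADII", "5E16.8",
                         [r / 0.1 for r in spec.gb_radii], 5, E)
            _fmt_section(fh, "SCREEN", "5E16.8", list(spec.gb_screen), 5, E)


def write_toy_inpcrd(positions_nm, path, box: TriclinicBox | None = None):
    pos = np.asarray(positions_nm, dtype=float) / 0.1  # nm -> A
    n = len(pos)
    with open(path, "w") as fh:
        fh.write("toy\n")
        fh.write(f"{n:5d}\n")
        flat = pos.reshape(-1)
        for start in range(0, len(flat), 6):
            fh.write("".join(f"{v:12.7f}" for v in flat[start:start + 6]) + "\n")
        if box is not None:
            from .amberio import _box_to_lengths_angles
            la, lb, lc, al, be, ga = _box_to_lengths_angles(box)
            fh.write("".join(f"{v:12.7f}" for v in (la, lb, lc, al, be, ga)) + "\n")


# ---------------------------------------------------------------------------
# independent brute-force reference
# ---------------------------------------------------------------------------

def reference_energy(description: dict, positions) -> tuple[dict, np.ndarray]:
    """Naive scalar-loop energies and finite-difference forces.

    ``description`` holds plain parameter lists (no engine objects):
      ``bonds``: (i, j, k, r0) — E = k (r-r0)^2
      ``angles``: (i, j, k_atom, k, theta0) — E = k (theta-theta0)^2
      ``torsions``: (i, j, k, l, k, n, gamma) — E = k (1+cos(n phi - gamma))
      ``charge``/``sigma``/``epsilon``: per-atom nonbonded parameters
      ``exclusions``: pair set; ``exceptions``: (i, j, qq, sig, eps)
      ``obc``: dict(charges, radii, screen, solvent_dielectric, sa) (optional)

    Forces are central finite differences of the total energy (h = 1e-6 nm),
    an independent check path with no analytic gradients at all.
    """
    pos = np.asarray(positions, dtype=float)

    def total(p):
        cats = _reference_categories(description, p)
        return sum(cats.values())

    categories = _reference_categories(description, pos)
    categories["Total"] = sum(categories.values())
    h = 1e-6
    forces = np.zeros_like(pos)
    for i in range(pos.shape[0]):
        for d in range(3):
            pp = pos.copy()
            pp[i, d] += h
            ep = total(pp)
            pp[i, d] -= 2 * h
            em = total(pp)
            forces[i, d] = -(ep - em) / (2 * h)
    return categories, forces


def _reference_categories(desc: dict, pos: np.ndarray) -> dict:
    out = {}
    e = 0.0
    for (i, j, k, r0) in desc.get("bonds", []):
        r = math.dist(pos[i], pos[j])
        e += k * (r - r0) ** 2
    out["Bond"] = e
    e = 0.0
    for (i, j, kk, k, t0) in desc.get("angles", []):
        u = pos[i] - pos[j]
        w = pos[kk] - pos[j]
        ct = float(np.dot(u, w) / (np.linalg.norm(u) * np.linalg.norm(w)))
        theta = math.acos(max(-1.0, min(1.0, ct)))
        e += k * (theta - t0) ** 2
    out["Angle"] = e
    e = 0.0
    for (i, j, kk, l, k, n, gamma) in desc.get("torsions", []):
        # projection construction for the signed (IUPAC) dihedral
        b0 = pos[i] - pos[j]
        axis = pos[kk] - pos[j]
        axis = axis / np.linalg.norm(axis)
        b2v = pos[l] - pos[kk]
        v = b0 - float(np.dot(b0, axis)) * axis
        w = b2v - float(np.dot(b2v, axis)) * axis
        phi = math.atan2(float(np.dot(np.cross(axis, v), w)), float(np.dot(v, w)))
        e += k * (1.0 + math.cos(n * phi - gamma))
    out["Dihedral"] = e
    q = desc.get("charge")
    if q is not None:
        sig = desc["sigma"]
        eps = desc["epsilon"]
        excl = {(min(a, b), max(a, b)) for a, b in desc.get("exclusions", [])}
        exc = {(min(i, j), max(i, j)): (qq, s, ep)
               for (i, j, qq, s, ep) in desc.get("exceptions", [])}
        n = len(q)
        e = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                if (i, j) in excl and (i, j) not in exc:
                    continue
                r = math.dist(pos[i], pos[j])
                if (i, j) in exc:
                    qq, s, ep = exc[(i, j)]
                else:
                    qq = q[i] * q[j]
                    s = 0.5 * (sig[i] + sig[j])
                    ep = math.sqrt(eps[i] * eps[j])
                sr6 = (s / r) ** 6
                e += 4.0 * ep * (sr6 * sr6 - sr6) + 138.935456 * qq / r
        out["Nonbonded"] = e
    obc = desc.get("obc")
    if obc is not None:
        out["OBC"] = _reference_obc(obc, pos)
    return out


def _reference_obc(obc: dict, pos: np.ndarray) -> float:
    """Scalar-loop OBC1 energy written straight from the published formulas."""
    q = obc["charges"]
    R = obc["radii"]
    S = obc["screen"]
    eps_out = obc.get("solvent_dielectric", 78.5)
    n = len(q)
    offset = 0.009
    rho = [R[i] - offset for i in range(n)]
    B = []
    for i in range(n):
        acc = 0.0
        for j in range(n):
            if i == j:
                continue
            r = math.dist(pos[i], pos[j])
            sr = S[j] * rho[j]
            if rho[i] >= r + sr:
                continue
            L = max(rho[i], abs(r - sr))
            U = r + sr
            term = (1.0 / L - 1.0 / U
                    + 0.25 * r * (1.0 / U**2 - 1.0 / L**2)
                    + 0.5 / r * math.log(L / U)
                    + 0.25 * sr * sr / r * (1.0 / L**2 - 1.0 / U**2))
            if rho[i] < sr - r:
                term += 2.0 * (1.0 / rho[i] - 1.0 / L)
            acc += term
        psi = 0.5 * acc * rho[i]
        h = 0.8 * psi + 2.909125 * psi**3
        B.append(1.0 / (1.0 / rho[i] - math.tanh(h) / R[i]))
    pref = -138.935456 * (1.0 - 1.0 / eps_out)
    e = 0.0
    for i in range(n):
        e += 0.5 * pref * q[i] * q[i] / B[i]
        for j in range(i + 1, n):
            r2 = float(np.sum((pos[i] - pos[j]) ** 2))
            fgb = math.sqrt(r2 + B[i] * B[j] * math.exp(-r2 / (4.0 * B[i] * B[j])))
            e += pref * q[i] * q[j] / fgb
    if obc.get("sa"):
        for i in range(n):
            e += 2.25936 * 4.0 * math.pi * (R[i] + 0.14) ** 2 * (R[i] / B[i]) ** 6
    return e
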