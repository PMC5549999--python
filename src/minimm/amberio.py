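"""Amber prmtop/inpcrd input pipeline and a minimal PDB reader/writer.

The prmtop format is a sequence of ``%FLAG`` sections, each with a Fortran
``%FORMAT`` record describing fixed-width fields.  Unit conventions follow
Amber: coordinates and radii in Angstrom, bond constants in kcal/mol/A^2,
angle/dihedral constants in kcal/mol, charges pre-scaled by 18.2223
(sqrt of the Coulomb constant in Amber's internal units).  Everything is
converted on input to the engine's nm / kJ/mol / elementary-charge system.

Explicit-solvent PME systems are refused rather than approximated: this
engine computes implicit-solvent (OBC1) and vacuum energies only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .forces import (
    HarmonicAngleTerm,
    HarmonicBondTerm,
    NonbondedParams,
    NonbondedTerm,
    OBCTerm,
    PeriodicTorsionTerm,
)
from .geometry import TriclinicBox, reduce_box
from .system import ConstraintDef, System

__all__ = [
    "PrmtopData",
    "InpcrdData",
    "read_prmtop",
    "read_inpcrd",
    "system_from_prmtop",
    "read_pdb",
    "write_pdb",
    "AMBER_CHARGE_SCALE",
    "KCAL_TO_KJ",
]

AMBER_CHARGE_SCALE = 18.2223
KCAL_TO_KJ = 4.184
ANGSTROM_TO_NM = 0.1
DEFAULT_SCEE = 1.2
DEFAULT_SCNB = 2.0

_FORMAT_RE = re.compile(r"\((\d+)[aIEFed](\d+)(?:\.\d+)?\)", re.IGNORECASE)
_KIND_RE = re.compile(r"\(\d+([aIEFed])", re.IGNORECASE)


class PrmtopError(ValueError):
    pass


@dataclass
class PrmtopData:
    """Parsed prmtop sections with Amber conventions still in place.

    ``charges`` are stored Amber-scaled; use :meth:`unscaled_charges` for
    values in elementary charge units.  Index arrays keep the raw Amber
    encoding (3*index, sign markers) — the decode helpers below apply the
    conventions.
    """

    sections: dict = field(default_factory=dict)

    @property
    def pointers(self):
        return self.sections["POINTERS"]

    @property
    def n_atoms(self) -> int:
        return int(self.pointers[0])

    @property
    def n_types(self) -> int:
        return int(self.pointers[1])

    @property
    def has_box(self) -> bool:
        return len(self.pointers) > 27 and int(self.pointers[27]) > 0

    @property
    def atom_names(self):
        return self.sections["ATOM_NAME"]

    @property
    def masses(self):
        return np.asarray(self.sections["MASS"], dtype=float)

    @property
    def charges(self):
        return np.asarray(self.sections["CHARGE"], dtype=float)

    def unscaled_charges(self):
        return self.charges / AMBER_CHARGE_SCALE

    # -- decoded topology -------------------------------------------------

    def bonds(self, include_h=True, exclude_h=True):
        """(i, j, type) with 0-based atom indices and 0-based types."""
        out = []
        keys = []
        if include_h:
            keys.append("BONDS_INC_HYDROGEN")
        if exclude_h:
            keys.append("BONDS_WITHOUT_HYDROGEN")
        for key in keys:
            raw = self.sections.get(key, [])
            for n in range(0, len(raw), 3):
                i, j, t = raw[n:n + 3]
                out.append((abs(int(i)) // 3, abs(int(j)) // 3, int(t) - 1))
        return out

    def angles(self):
        out = []
        for key in ("ANGLES_INC_HYDROGEN", "ANGLES_WITHOUT_HYDROGEN"):
            raw = self.sections.get(key, [])
            for n in range(0, len(raw), 4):
                i, j, k, t = raw[n:n + 4]
                out.append((abs(int(i)) // 3, abs(int(j)) // 3,
                            abs(int(k)) // 3, int(t) - 1))
        return out

    def dihedrals(self):
        """(i, j, k, l, type, is_improper, skip_14) decoded per Amber rules.

        A negative third index marks a dihedral whose 1-4 interaction must
        not be counted (ring closure / multi-term duplicate); a negative
        fourth index marks an improper.
        """
        out = []
        for key in ("DIHEDRALS_INC_HYDROGEN", "DIHEDRALS_WITHOUT_HYDROGEN"):
            raw = self.sections.get(key, [])
            for n in range(0, len(raw), 5):
                i, j, k, l, t = raw[n:n + 5]
                skip_14 = int(k) < 0
                improper = int(l) < 0
                out.append((abs(int(i)) // 3, abs(int(j)) // 3, abs(int(k)) // 3,
                            abs(int(l)) // 3, int(t) - 1, improper, skip_14))
        return out

    def exclusion_pairs(self):
        counts = self.sections.get("NUMBER_EXCLUDED_ATOMS", [])
        flat = self.sections.get("EXCLUDED_ATOMS_LIST", [])
        pairs = set()
        pos = 0
        for i, c in enumerate(counts):
            for raw in flat[pos:pos + int(c)]:
                j = int(raw)
                if j > 0:  # 0 is the "no exclusions" placeholder
                    pairs.add((min(i, j - 1), max(i, j - 1)))
            pos += int(c)
        return pairs

    def lj_per_type(self):
        """Per-type (sigma nm, epsilon kJ/mol) from the diagonal A/B tables."""
        nt = self.n_types
        nbidx = self.sections["NONBONDED_PARM_INDEX"]
        A = self.sections["LENNARD_JONES_ACOEF"]
        B = self.sections["LENNARD_JONES_BCOEF"]
        sigma = np.empty(nt)
        eps = np.empty(nt)
        for t in range(nt):
            idx = int(nbidx[nt * t + t]) - 1
            a, b = float(A[idx]), float(B[idx])
            if a <= 0.0 or b <= 0.0:
                sigma[t] = 0.1
                eps[t] = 0.0
            else:
                sigma[t] = (a / b) ** (1.0 / 6.0) * ANGSTROM_TO_NM
                eps[t] = b * b / (4.0 * a) * KCAL_TO_KJ
        return sigma, eps


def _parse_format(fmt_line: str):
    m = _FORMAT_RE.search(fmt_line)
    if m is None:
        raise PrmtopError(f"cannot parse FORMAT record: {fmt_line.strip()!r}")
    kind = _KIND_RE.search(fmt_line).group(1).lower()
    return int(m.group(1)), kind, int(m.group(2))


def read_prmtop(path) -> PrmtopData:
    """Parse an Amber prmtop file (``%VERSION``/``%FLAG``/``%FORMAT`` layout)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    sections: dict = {}
    flag = None
    spec = None
    raw_lines: list[str] = []

    def finish():
        if flag is None:
            return
        count, kind, width = spec
        values: list = []
        for line in raw_lines:
            for start in range(0, len(line), width):
                fieldtxt = line[start:start + width]
                if not fieldtxt.strip() and kind != "a":
                    continue
                if kind == "a":
                    values.append(fieldtxt[:width].strip())
                elif kind == "i":
                    try:
                        values.append(int(fieldtxt))
                    except ValueError as err:
                        raise PrmtopError(
                            f"malformed integer field in {flag}: {fieldtxt!r}") from err
                else:
                    try:
                        values.append(float(fieldtxt.replace("D", "E").replace("d", "e")))
                    except ValueError as err:
                        raise PrmtopError(
                            f"malformed real field in {flag}: {fieldtxt!r}") from err
        sections[flag] = values

    for line in lines:
        if line.startswith("%VERSION") or line.startswith("%COMMENT"):
            continue
        if line.startswith("%FLAG"):
            finish()
            flag = line.split()[1]
            spec = None
            raw_lines = []
        elif line.startswith("%FORMAT"):
            spec = _parse_format(line)
        elif flag is not None:
            if spec is None:
                raise PrmtopError(f"data before FORMAT in section {flag}")
            raw_lines.append(line)
    finish()
    for mandatory in ("POINTERS", "ATOM_NAME", "CHARGE", "MASS"):
        if mandatory not in sections:
            raise PrmtopError(f"missing mandatory section {mandatory}")
    data = PrmtopData(sections)
    if len(data.masses) != data.n_atoms:
        raise PrmtopError("MASS section length disagrees with POINTERS")
    return data


@dataclass
class InpcrdData:
    positions: np.ndarray          # nm
    velocities: np.ndarray | None  # nm/ps
    box: TriclinicBox | None


def _box_from_lengths_angles(lengths_nm, angles_deg) -> TriclinicBox:
    la, lb, lc = lengths_nm
    alpha, beta, gamma = np.radians(angles_deg)
    a = np.array([la, 0.0, 0.0])
    b = np.array([lb * np.cos(gamma), lb * np.sin(gamma), 0.0])
    cx = lc * np.cos(beta)
    cy = lc * (np.cos(alpha) - np.cos(beta) * np.cos(gamma)) / np.sin(gamma)
    cz = np.sqrt(max(lc**2 - cx**2 - cy**2, 0.0))
    return reduce_box(a, b, np.array([cx, cy, cz]))


def read_inpcrd(path) -> InpcrdData:
    """Read an Amber restart/inpcrd file (fixed-width coordinate records)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 2:
        raise ValueError("inpcrd file too short")
    header = lines[1].split()
    natom = int(header[0])
    values: list[float] = []
    for line in lines[2:]:
        for start in range(0, len(line), 12):
            txt = line[start:start + 12]
            if txt.strip():
                values.append(float(txt))
    n = len(values)
    coords = 3 * natom
    vels = None
    box = None
    if n == coords:
        pass
    elif n == coords + 6:
        box = values[coords:]
    elif n == 2 * coords:
        vels = values[coords:]
    elif n == 2 * coords + 6:
        vels = values[coords:2 * coords]
        box = values[2 * coords:]
    else:
        raise ValueError(
            f"inpcrd value count {n} inconsistent with {natom} atoms")
    pos = np.array(values[:coords]).reshape(natom, 3) * ANGSTROM_TO_NM
    vel = None
    if vels is not None:
        # Amber velocity unit is A per 1/20.455 ps
        vel = np.array(vels).reshape(natom, 3) * ANGSTROM_TO_NM * 20.455
    tri = None
    if box is not None:
        tri = _box_from_lengths_angles(
            np.array(box[:3]) * ANGSTROM_TO_NM, box[3:])
    return InpcrdData(pos, vel, tri)


def system_from_prmtop(prmtop: PrmtopData, solvent: str = "vacuum",
                       constraints: str = "none", sa_term: bool = False,
                       solvent_dielectric: float = 78.5) -> System:
    """Build a :class:`System` with Amber functional forms from prmtop data.

    ``solvent`` is ``vacuum`` or ``obc1``; ``constraints`` is ``none``,
    ``h_bonds`` or ``all_bonds`` (converted bonds lose their harmonic term
    and gain a rigid constraint at the equilibrium length).
    """
    if solvent not in ("vacuum", "obc1"):
        if solvent in ("pme", "explicit"):
            raise ValueError(
                "explicit-solvent PME is out of scope for this engine; "
                "use solvent='obc1' or 'vacuum'")
        raise ValueError(f"unknown solvent model {solvent!r}")
    if constraints not in ("none", "h_bonds", "all_bonds"):
        raise ValueError(f"unknown constraints option {constraints!r}")
    sec = prmtop.sections
    n = prmtop.n_atoms
    masses = prmtop.masses
    q = prmtop.unscaled_charges()

    bond_k = np.asarray(sec.get("BOND_FORCE_CONSTANT", []), dtype=float) \
        * KCAL_TO_KJ / ANGSTROM_TO_NM**2
    bond_r0 = np.asarray(sec.get("BOND_EQUIL_VALUE", []), dtype=float) * ANGSTROM_TO_NM
    angle_k = np.asarray(sec.get("ANGLE_FORCE_CONSTANT", []), dtype=float) * KCAL_TO_KJ
    angle_t0 = np.asarray(sec.get("ANGLE_EQUIL_VALUE", []), dtype=float)
    dih_k = np.asarray(sec.get("DIHEDRAL_FORCE_CONSTANT", []), dtype=float) * KCAL_TO_KJ
    dih_n = np.asarray(sec.get("DIHEDRAL_PERIODICITY", []), dtype=float)
    dih_phase = np.asarray(sec.get("DIHEDRAL_PHASE", []), dtype=float)
    scee = np.asarray(sec.get("SCEE_SCALE_FACTOR", []), dtype=float)
    scnb = np.asarray(sec.get("SCNB_SCALE_FACTOR", []), dtype=float)

    h_bonds = prmtop.bonds(include_h=True, exclude_h=False)
    heavy_bonds = prmtop.bonds(include_h=False, exclude_h=True)

    cons: list[ConstraintDef] = []
    bond_items = []
    constrain_h = constraints in ("h_bonds", "all_bonds")
    constrain_all = constraints == "all_bonds"
    for group, constrained in ((h_bonds, constrain_h), (heavy_bonds, constrain_all)):
        for (i, j, t) in group:
            if constrained:
                cons.append(ConstraintDef(i, j, float(bond_r0[t])))
            else:
                bond_items.append((i, j, float(bond_k[t]), float(bond_r0[t])))

    angle_items = [(i, j, k, float(angle_k[t]), float(angle_t0[t]))
                   for (i, j, k, t) in prmtop.angles()]

    torsion_items = []
    pairs_14 = {}
    for (i, j, k, l, t, improper, skip_14) in prmtop.dihedrals():
        per = max(1, int(round(abs(dih_n[t]))))
        torsion_items.append((i, j, k, l, float(dih_k[t]), per, float(dih_phase[t])))
        if not improper and not skip_14:
            key = (min(i, l), max(i, l))
            if key not in pairs_14:
                e = scee[t] if len(scee) else DEFAULT_SCEE
                nbsc = scnb[t] if len(scnb) else DEFAULT_SCNB
                pairs_14[key] = (float(e) if e > 0 else DEFAULT_SCEE,
                                 float(nbsc) if nbsc > 0 else DEFAULT_SCNB)

    sigma_t, eps_t = prmtop.lj_per_type()
    type_idx = np.asarray(sec["ATOM_TYPE_INDEX"], dtype=int) - 1
    sigma = sigma_t[type_idx]
    eps = eps_t[type_idx]

    exclusions = prmtop.exclusion_pairs()
    exceptions = []
    for (i, j), (e_scale, nb_scale) in sorted(pairs_14.items()):
        qq = q[i] * q[j] / e_scale
        sig = 0.5 * (sigma[i] + sigma[j])
        epsij = np.sqrt(eps[i] * eps[j]) / nb_scale
        exceptions.append((i, j, qq, sig, epsij))
        exclusions.add((i, j))

    params = NonbondedParams(q, sigma, eps, exceptions=exceptions,
                             exclusions=exclusions)
    terms = [
        HarmonicBondTerm(bond_items),
        HarmonicAngleTerm(angle_items),
        PeriodicTorsionTerm(torsion_items),
        NonbondedTerm(params),
    ]
    if solvent == "obc1":
        if "RADII" not in sec or "SCREEN" not in sec:
            raise PrmtopError("prmtop lacks RADII/SCREEN sections needed for obc1")
        radii = np.asarray(sec["RADII"], dtype=float) * ANGSTROM_TO_NM
        screen = np.asarray(sec["SCREEN"], dtype=float)
        terms.append(OBCTerm(q, radii, screen, sa_term=sa_term,
                             solvent_dielectric=solvent_dielectric))
    return System(masses, constraints=cons, force_terms=terms)


# ---------------------------------------------------------------------------
# PDB (minimal ATOM/HETATM/CRYST1 subset)
# ---------------------------------------------------------------------------

def read_pdb(path):
    """Return (names, elements, positions nm) from ATOM/HETATM records."""
    names, elements, coords = [], [], []
    with open(path) as fh:
        for line in fh:
            if not (line.startswith("ATOM") or line.startswith("HETATM")):
                continue
            if len(line) < 54:
                raise ValueError(f"malformed PDB record: {line.rstrip()!r}")
            name = line[12:16].strip()
            try:
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
            except ValueError as err:
                raise ValueError(f"malformed coordinates: {line.rstrip()!r}") from err
            element = line[76:78].strip() if len(line) >= 78 else ""
            if not element:
                # fall back to the leading letters of the atom name
                element = re.sub(r"[^A-Za-z].*$", "", name)[:2].strip()
                if len(element) == 2 and element[1].isupper():
                    element = element[0]
            names.append(name)
            elements.append(element.capitalize())
            coords.append((x, y, z))
    return names, elements, np.array(coords) * ANGSTROM_TO_NM


def write_pdb(path, names, positions_nm, elements=None, box=None):
    """Write fixed-width ATOM records (coordinates nm -> Angstrom)."""
    positions = np.asarray(positions_nm, dtype=float) / ANGSTROM_TO_NM
    with open(path, "w") as fh:
        if box is not None:
            la, lb, lc, al, be, ga = _box_to_lengths_angles(box)
            fh.write(f"CRYST1{la:9.3f}{lb:9.3f}{lc:9.3f}"
                     f"{al:7.2f}{be:7.2f}{ga:7.2f} P 1           1\n")
        for i, (name, (x, y, z)) in enumerate(zip(names, positions), start=1):
            el = (elements[i - 1] if elements is not None else name[:1]).rjust(2)
            pname = name if len(name) == 4 else f" {name:<3s}"
            fh.write(f"ATOM  {i:5d} {pname:<4.4s} MOL A   1    "
                     f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          {el:>2s}\n")
        fh.write("END\n")


def _box_to_lengths_angles(box: TriclinicBox):
    m = box.matrix / ANGSTROM_TO_NM
    la, lb, lc = (np.linalg.norm(m[i]) for i in range(3))
    alpha = np.degrees(np.arccos(np.dot(m[1], m[2]) / (lb * lc)))
    beta = np.degrees(np.arccos(np.dot(m[0], m[2]) / (la * lc)))
    gamma = np.degrees(np.arccos(np.dot(m[0], m[1]) / (la * lb)))
    return la, lb, lc, alpha, beta, gamma
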