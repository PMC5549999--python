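"""Force terms: standard Amber forms, expression-defined custom terms, OBC.

Every term implements ``energy_and_forces(positions, box) -> (E, F)`` with
energies in kJ/mol and forces in kJ/mol/nm, forces being exactly -grad E.
Custom terms are driven by the :mod:`minimm.expr` machinery: the user's
energy expression is differentiated analytically with respect to the
geometric variable (bond length r, angle theta, dihedral theta, or raw
coordinates) and the chain rule distributes the force onto the atoms.

Pair loops are plain O(N^2) — correctness-first desk scale, with cutoff
filtering applied per pair and the minimum image convention when a periodic
box is attached.
"""

from __future__ import annotations

import numpy as np

from . import expr as _expr
from .geometry import TriclinicBox, minimum_image_many
from .system import COULOMB_CONSTANT

__all__ = [
    "HarmonicBondTerm",
    "HarmonicAngleTerm",
    "PeriodicTorsionTerm",
    "NonbondedTerm",
    "NonbondedParams",
    "OBCTerm",
    "CustomBondTerm",
    "CustomAngleTerm",
    "CustomTorsionTerm",
    "CustomExternalTerm",
    "CustomNonbondedTerm",
    "CustomCompoundBondTerm",
    "CustomCentroidBondTerm",
    "standard_bonded_terms",
]

_MIN_SIN = 1e-8  # regularizer for angle forces at theta = 0 or pi


# ---------------------------------------------------------------------------
# vectorized geometric primitives and their gradients
# ---------------------------------------------------------------------------

def _disp(pos, i, j, box):
    """Displacement r_j - r_i with minimum image when periodic."""
    return minimum_image_many(box, pos[j] - pos[i])


def _bond_geom(pos, i, j, box):
    dr = _disp(pos, i, j, box)
    r = np.linalg.norm(dr, axis=1)
    u = dr / np.maximum(r, 1e-300)[:, None]
    # dr/dr_i = -u, dr/dr_j = +u
    return r, u


def _angle_geom(pos, i, j, k, box):
    """Angle at j.  Returns theta and dtheta/dr_{i,j,k}."""
    u = _disp(pos, j, i, box)
    w = _disp(pos, j, k, box)
    lu = np.linalg.norm(u, axis=1)
    lw = np.linalg.norm(w, axis=1)
    uh = u / lu[:, None]
    wh = w / lw[:, None]
    cos_t = np.clip(np.einsum("nd,nd->n", uh, wh), -1.0, 1.0)
    theta = np.arccos(cos_t)
    sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), _MIN_SIN)
    di = (cos_t[:, None] * uh - wh) / (lu * sin_t)[:, None]
    dk = (cos_t[:, None] * wh - uh) / (lw * sin_t)[:, None]
    dj = -(di + dk)
    return theta, di, dj, dk


def _dihedral_geom(pos, i, j, k, l, box):
    """Signed dihedral (IUPAC, range (-pi, pi]) and its four gradients."""
    b1 = _disp(pos, i, j, box)
    b2 = _disp(pos, j, k, box)
    b3 = _disp(pos, k, l, box)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    lb2 = np.linalg.norm(b2, axis=1)
    b2h = b2 / lb2[:, None]
    y = np.einsum("nd,nd->n", np.cross(n1, n2), b2h)
    x = np.einsum("nd,nd->n", n1, n2)
    phi = np.arctan2(y, x)
    n1sq = np.maximum(np.einsum("nd,nd->n", n1, n1), 1e-300)
    n2sq = np.maximum(np.einsum("nd,nd->n", n2, n2), 1e-300)
    di = -(lb2 / n1sq)[:, None] * n1
    dl = (lb2 / n2sq)[:, None] * n2
    d12 = np.einsum("nd,nd->n", b1, b2) / lb2**2
    d32 = np.einsum("nd,nd->n", b3, b2) / lb2**2
    dj = -(1.0 + d12)[:, None] * di + d32[:, None] * dl
    dk = d12[:, None] * di - (1.0 + d32)[:, None] * dl
    return phi, di, dj, dk, dl


def _scatter(forces, idx, contrib):
    np.add.at(forces, idx, contrib)


# ---------------------------------------------------------------------------
# standard bonded terms (Amber functional forms)
# ---------------------------------------------------------------------------

class HarmonicBondTerm:
    """E = sum k (r - r0)^2 (Amber convention: no 1/2)."""

    category = "Bond"

    def __init__(self, bonds):
        """``bonds``: iterable of (i, j, k [kJ/mol/nm^2], r0 [nm])."""
        bonds = list(bonds)
        self.i = np.array([b[0] for b in bonds], dtype=int)
        self.j = np.array([b[1] for b in bonds], dtype=int)
        self.k = np.array([b[2] for b in bonds], dtype=float)
        self.r0 = np.array([b[3] for b in bonds], dtype=float)

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        if len(self.i) == 0:
            return 0.0, forces
        r, u = _bond_geom(positions, self.i, self.j, box)
        delta = r - self.r0
        energy = float(np.sum(self.k * delta**2))
        dEdr = 2.0 * self.k * delta
        _scatter(forces, self.i, dEdr[:, None] * u)
        _scatter(forces, self.j, -dEdr[:, None] * u)
        return energy, forces


class HarmonicAngleTerm:
    """E = sum k (theta - theta0)^2."""

    category = "Angle"

    def __init__(self, angles):
        """``angles``: iterable of (i, j, k_atom, k [kJ/mol/rad^2], theta0)."""
        angles = list(angles)
        self.i = np.array([a[0] for a in angles], dtype=int)
        self.j = np.array([a[1] for a in angles], dtype=int)
        self.k_atom = np.array([a[2] for a in angles], dtype=int)
        self.k = np.array([a[3] for a in angles], dtype=float)
        self.theta0 = np.array([a[4] for a in angles], dtype=float)

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        if len(self.i) == 0:
            return 0.0, forces
        theta, di, dj, dk = _angle_geom(positions, self.i, self.j, self.k_atom, box)
        delta = theta - self.theta0
        energy = float(np.sum(self.k * delta**2))
        dEdt = (2.0 * self.k * delta)[:, None]
        _scatter(forces, self.i, -dEdt * di)
        _scatter(forces, self.j, -dEdt * dj)
        _scatter(forces, self.k_atom, -dEdt * dk)
        return energy, forces


class PeriodicTorsionTerm:
    """E = sum k (1 + cos(n*phi - gamma))."""

    category = "Dihedral"

    def __init__(self, torsions):
        """``torsions``: iterable of (i, j, k, l, k [kJ/mol], n, gamma)."""
        torsions = list(torsions)
        for t in torsions:
            if t[5] < 1:
                raise ValueError("torsion periodicity must be >= 1")
        self.idx = np.array([t[:4] for t in torsions], dtype=int).reshape(-1, 4)
        self.k = np.array([t[4] for t in torsions], dtype=float)
        self.n = np.array([t[5] for t in torsions], dtype=float)
        self.gamma = np.array([t[6] for t in torsions], dtype=float)

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        if len(self.k) == 0:
            return 0.0, forces
        i, j, k, l = self.idx.T
        phi, di, dj, dk, dl = _dihedral_geom(positions, i, j, k, l, box)
        arg = self.n * phi - self.gamma
        energy = float(np.sum(self.k * (1.0 + np.cos(arg))))
        dEdphi = (-self.k * self.n * np.sin(arg))[:, None]
        _scatter(forces, i, -dEdphi * di)
        _scatter(forces, j, -dEdphi * dj)
        _scatter(forces, k, -dEdphi * dk)
        _scatter(forces, l, -dEdphi * dl)
        return energy, forces


def standard_bonded_terms(bonds, angles, torsions):
    """Build the three Amber bonded terms; categories stay separable."""
    return [HarmonicBondTerm(bonds), HarmonicAngleTerm(angles),
            PeriodicTorsionTerm(torsions)]


# ---------------------------------------------------------------------------
# standard nonbonded term
# ---------------------------------------------------------------------------

class NonbondedParams:
    """Per-particle charge/sigma/epsilon plus exceptions and exclusions.

    Exceptions are explicit (i, j, chargeprod, sigma, epsilon) entries that
    fully replace the default pair interaction (Amber 1-4 scaling is
    materialized this way); excluded pairs contribute nothing.
    """

    def __init__(self, charge, sigma, epsilon, exceptions=(), exclusions=()):
        self.charge = np.asarray(charge, dtype=float)
        self.sigma = np.asarray(sigma, dtype=float)
        self.epsilon = np.asarray(epsilon, dtype=float)
        if np.any(self.epsilon < 0):
            raise ValueError("epsilon must be non-negative")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be positive")
        self.exclusions = {(min(i, j), max(i, j)) for i, j in exclusions}
        self.exceptions = []
        seen = set()
        for (i, j, qq, sig, eps) in exceptions:
            key = (min(i, j), max(i, j))
            if key in seen:
                raise ValueError(f"duplicate exception for pair {key}")
            seen.add(key)
            self.exceptions.append((key[0], key[1], float(qq), float(sig), float(eps)))


def _lj_coulomb(r, qq, sig, eps):
    """Energy and dE/dr for LJ 12-6 plus Coulomb at separations r."""
    inv_r = 1.0 / r
    sr6 = (sig * inv_r) ** 6
    e_lj = 4.0 * eps * (sr6**2 - sr6)
    e_c = COULOMB_CONSTANT * qq * inv_r
    dEdr = (-4.0 * eps * (12.0 * sr6**2 - 6.0 * sr6) - COULOMB_CONSTANT * qq * inv_r) * inv_r
    return e_lj + e_c, dEdr


class NonbondedTerm:
    """LJ 12-6 (Lorentz-Berthelot) + Coulomb over all non-excluded pairs."""

    category = "Nonbonded"

    def __init__(self, params: NonbondedParams, cutoff: float | None = None,
                 periodic: bool = False):
        self.params = params
        self.cutoff = cutoff
        self.periodic = periodic
        n = len(params.charge)
        ii, jj = np.triu_indices(n, k=1)
        skip = params.exclusions | {(e[0], e[1]) for e in params.exceptions}
        if skip:
            keep = np.array([(int(a), int(b)) not in skip for a, b in zip(ii, jj)])
            ii, jj = ii[keep], jj[keep]
        self.ii, self.jj = ii, jj

    def _check_cutoff(self, box):
        if self.periodic and self.cutoff is not None and box is not None:
            if self.cutoff > box.inscribed_sphere_diameter() / 2:
                raise ValueError("cutoff exceeds half the box inscribed-sphere diameter")

    def energy_and_forces(self, positions, box=None):
        p = self.params
        forces = np.zeros_like(positions)
        use_box = box if self.periodic else None
        self._check_cutoff(box)
        energy = 0.0
        if len(self.ii):
            dr = minimum_image_many(use_box, positions[self.jj] - positions[self.ii])
            r = np.linalg.norm(dr, axis=1)
            qq = p.charge[self.ii] * p.charge[self.jj]
            sig = 0.5 * (p.sigma[self.ii] + p.sigma[self.jj])
            eps = np.sqrt(p.epsilon[self.ii] * p.epsilon[self.jj])
            mask = np.ones(len(r), dtype=bool) if self.cutoff is None else (r < self.cutoff)
            e, dEdr = _lj_coulomb(r[mask], qq[mask], sig[mask], eps[mask])
            energy += float(np.sum(e))
            fpair = (-dEdr / r[mask])[:, None] * dr[mask]
            _scatter(forces, self.jj[mask], fpair)
            _scatter(forces, self.ii[mask], -fpair)
        for (i, j, qq, sig, eps) in p.exceptions:
            dr = minimum_image_many(use_box, positions[j][None] - positions[i][None])[0]
            r = float(np.linalg.norm(dr))
            if self.cutoff is not None and r >= self.cutoff:
                continue
            e, dEdr = _lj_coulomb(np.array([r]), np.array([qq]),
                                  np.array([sig]), np.array([eps]))
            energy += float(e[0])
            fpair = -float(dEdr[0]) / r * dr
            forces[j] += fpair
            forces[i] -= fpair
        return energy, forces


# ---------------------------------------------------------------------------
# OBC generalized Born implicit solvent
# ---------------------------------------------------------------------------

class OBCTerm:
    """Onufriev-Bashford-Case generalized Born solvation (OBC1 variant).

    Born radii come from pairwise HCT descreening integrals with the OBC
    tanh rescaling (alpha=0.8, beta=0, gamma=2.909125 for OBC1); pair
    energies use the canonical GB smoothing function
    f = sqrt(r^2 + Bi*Bj*exp(-r^2/(4*Bi*Bj))).  The optional ACE surface-area
    term approximates the nonpolar contribution.
    """

    category = "OBC"

    OFFSET = 0.009          # nm, dielectric offset
    ALPHA, BETA, GAMMA = 0.8, 0.0, 2.909125
    PROBE_RADIUS = 0.14     # nm
    SA_FACTOR = 2.25936     # kJ/mol/nm^2 (ACE surface tension * 4*pi folded in below)

    def __init__(self, charges, gb_radii, screening, solute_dielectric=1.0,
                 solvent_dielectric=78.5, sa_term=False):
        self.q = np.asarray(charges, dtype=float)
        self.R = np.asarray(gb_radii, dtype=float)
        if np.any(self.R <= 0):
            raise ValueError("GB radii must be positive")
        self.S = np.asarray(screening, dtype=float)
        self.eps_in = solute_dielectric
        self.eps_out = solvent_dielectric
        self.sa_term = sa_term
        self.rho = self.R - self.OFFSET
        if np.any(self.rho <= 0):
            raise ValueError("GB radius must exceed the dielectric offset")
        self.prefactor = -COULOMB_CONSTANT * (1.0 / self.eps_in - 1.0 / self.eps_out)

    # -- Born radii -------------------------------------------------------

    def _descreen_terms(self, r):
        """HCT integral term_ij (descreening of i by j) and d(term)/dr.

        ``r`` is the full NxN distance matrix (diagonal ignored).
        """
        n = len(self.q)
        rho_i = self.rho[:, None] * np.ones((1, n))
        sr_j = (self.S * self.rho)[None, :] * np.ones((n, 1))
        np.fill_diagonal(r, 1.0)  # dummy to avoid 0-division; masked out below
        U = r + sr_j
        absdiff = np.abs(r - sr_j)
        L = np.maximum(rho_i, absdiff)
        inv_L, inv_U, inv_r = 1.0 / L, 1.0 / U, 1.0 / r
        term = (inv_L - inv_U
                + 0.25 * r * (inv_U**2 - inv_L**2)
                + 0.5 * inv_r * np.log(L * inv_U)
                + 0.25 * sr_j**2 * inv_r * (inv_L**2 - inv_U**2))
        buried = rho_i < (sr_j - r)
        term = term + np.where(buried, 2.0 * (1.0 / rho_i - inv_L), 0.0)
        # derivative wrt r
        dL = np.where(absdiff > rho_i, np.sign(r - sr_j), 0.0)
        dterm = (-dL * inv_L**2 + inv_U**2
                 + 0.25 * (inv_U**2 - inv_L**2)
                 + 0.5 * r * (-inv_U**3 + inv_L**3 * dL)
                 - 0.5 * inv_r**2 * np.log(L * inv_U)
                 + 0.5 * inv_r * (dL * inv_L - inv_U)
                 - 0.25 * sr_j**2 * inv_r**2 * (inv_L**2 - inv_U**2)
                 + 0.25 * sr_j**2 * inv_r * (-2.0 * inv_L**3 * dL + 2.0 * inv_U**3))
        dterm = dterm + np.where(buried, 2.0 * dL * inv_L**2, 0.0)
        active = rho_i < U
        np.fill_diagonal(active, False)
        term = np.where(active, term, 0.0)
        dterm = np.where(active, dterm, 0.0)
        return term, dterm

    def born_radii(self, positions):
        """Effective Born radii (nm) plus intermediates for the gradient."""
        pos = np.asarray(positions, dtype=float)
        diff = pos[:, None, :] - pos[None, :, :]
        r = np.sqrt(np.maximum(np.einsum("ijd,ijd->ij", diff, diff), 0.0))
        term, dterm = self._descreen_terms(r.copy())
        I = 0.5 * np.sum(term, axis=1)
        psi = I * self.rho
        h = self.ALPHA * psi - self.BETA * psi**2 + self.GAMMA * psi**3
        tanh_h = np.tanh(h)
        inv_B = 1.0 / self.rho - tanh_h / self.R
        B = 1.0 / inv_B
        # dB/dpsi for the chain rule
        dh = self.ALPHA - 2.0 * self.BETA * psi + 3.0 * self.GAMMA * psi**2
        dB_dpsi = B**2 * (1.0 - tanh_h**2) * dh / self.R
        return B, dB_dpsi, dterm, r, diff

    # -- energy and forces ------------------------------------------------

    def energy_and_forces(self, positions, box=None):
        n = len(self.q)
        B, dB_dpsi, dterm, r, diff = self.born_radii(positions)
        q = self.q
        D = self.prefactor  # negative of the usual positive constant folded in
        np.fill_diagonal(r, 1.0)
        BB = B[:, None] * B[None, :]
        u = np.exp(-r**2 / (4.0 * BB))
        f2 = r**2 + BB * u
        f = np.sqrt(f2)
        qq = q[:, None] * q[None, :]
        pair_mat = qq / f
        off = ~np.eye(n, dtype=bool)
        e_cross = 0.5 * D * np.sum(pair_mat[off])
        e_self = 0.5 * D * np.sum(q**2 / B)
        energy = e_cross + e_self

        # dE/dB_i: self part + cross part (full row, both orderings summed)
        dE_dB = -0.5 * D * q**2 / B**2
        df_dBi = u * (B[None, :] + r**2 / (4.0 * B[:, None])) / (2.0 * f)
        contrib = -0.5 * D * qq / f2 * df_dBi
        contrib[~off] = 0.0
        dE_dB = dE_dB + 2.0 * np.sum(contrib, axis=1)

        if self.sa_term:
            sa_each = self.SA_FACTOR * 4.0 * np.pi * (self.R + self.PROBE_RADIUS) ** 2 \
                * (self.R / B) ** 6
            energy += float(np.sum(sa_each))
            dE_dB = dE_dB - 6.0 * sa_each / B

        # direct r-dependence of the pair smoothing function
        df_dr = r * (1.0 - 0.25 * u) / f
        w_direct = -0.5 * D * qq / f2 * df_dr
        w_direct[~off] = 0.0

        # chain through Born radii: dpsi_i/dr_ij = rho_i * 0.5 * dterm_ij
        w_born = (dE_dB * dB_dpsi * self.rho)[:, None] * 0.5 * dterm
        # row a must carry the FULL d E/d r_ab of each unordered pair:
        # both orderings of the direct part plus both Born chains
        w_total = w_direct + w_direct.T + w_born + w_born.T

        inv_r = 1.0 / r
        np.fill_diagonal(inv_r, 0.0)
        # force on atom a: sum_b w_total[a,b] * (diff[a,b]/r) (gradient descent sign)
        grad = np.einsum("ab,abd->ad", w_total * inv_r, diff)
        forces = -grad
        return float(energy), forces


# ---------------------------------------------------------------------------
# custom (expression-defined) terms
# ---------------------------------------------------------------------------

class _CustomItemTerm:
    """Shared machinery: energy expression over one geometric variable."""

    geom_var: str = "r"

    def __init__(self, energy, per_item_parameter_names=(), items=(),
                 global_parameters=None, category="Other"):
        self.category = category
        pe = energy if isinstance(energy, _expr.ParsedExpression) else _expr.parse(energy)
        self.param_names = list(per_item_parameter_names)
        self.globals = dict(global_parameters or {})
        allowed = {self.geom_var} | set(self.param_names) | set(self.globals)
        unknown = pe.free_variables - allowed
        if unknown:
            raise ValueError(f"expression references unknown variables {sorted(unknown)}")
        order = [self.geom_var] + self.param_names + sorted(self.globals)
        self._fn = _expr.compile_function(pe, order)
        self._dfn = _expr.compile_function(_expr.differentiate(pe, self.geom_var), order)
        self.atom_idx, self.param_values = self._unpack_items(items)

    def _unpack_items(self, items):
        idx_rows, val_rows = [], []
        for item in items:
            atoms, values = item
            values = list(values)
            if len(values) != len(self.param_names):
                raise ValueError("parameter table width mismatch")
            idx_rows.append(list(np.atleast_1d(atoms)))
            val_rows.append(values)
        idx = np.array(idx_rows, dtype=int) if idx_rows else np.zeros((0, self.n_atoms_per_item), dtype=int)
        vals = np.array(val_rows, dtype=float) if val_rows else np.zeros((0, len(self.param_names)))
        return idx, vals

    n_atoms_per_item = 2

    def _eval(self, geom):
        args = [geom] + [self.param_values[:, i] for i in range(len(self.param_names))] \
            + [self.globals[k] for k in sorted(self.globals)]
        e = self._fn(*args)
        dEdg = self._dfn(*args)
        return np.atleast_1d(e), np.atleast_1d(dEdg)


class CustomBondTerm(_CustomItemTerm):
    """Energy expression in the inter-atom distance ``r`` (nm) per bond."""

    geom_var = "r"
    n_atoms_per_item = 2

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        if len(self.atom_idx) == 0:
            return 0.0, forces
        i, j = self.atom_idx.T
        r, u = _bond_geom(positions, i, j, box)
        e, dEdr = self._eval(r)
        _scatter(forces, i, dEdr[:, None] * u)
        _scatter(forces, j, -dEdr[:, None] * u)
        return float(np.sum(e)), forces


class CustomAngleTerm(_CustomItemTerm):
    """Energy expression in the angle ``theta`` (radians) per triplet."""

    geom_var = "theta"
    n_atoms_per_item = 3

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        if len(self.atom_idx) == 0:
            return 0.0, forces
        i, j, k = self.atom_idx.T
        theta, di, dj, dk = _angle_geom(positions, i, j, k, box)
        e, dEdt = self._eval(theta)
        for idx, grad in ((i, di), (j, dj), (k, dk)):
            _scatter(forces, idx, -dEdt[:, None] * grad)
        return float(np.sum(e)), forces


class CustomTorsionTerm(_CustomItemTerm):
    """Energy expression in the signed dihedral ``theta`` per quadruplet."""

    geom_var = "theta"
    n_atoms_per_item = 4

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        if len(self.atom_idx) == 0:
            return 0.0, forces
        i, j, k, l = self.atom_idx.T
        phi, di, dj, dk, dl = _dihedral_geom(positions, i, j, k, l, box)
        e, dEdp = self._eval(phi)
        for idx, grad in ((i, di), (j, dj), (k, dk), (l, dl)):
            _scatter(forces, idx, -dEdp[:, None] * grad)
        return float(np.sum(e)), forces


class CustomExternalTerm:
    """Per-particle energy expression in the raw coordinates x, y, z (nm)."""

    category = "Other"

    def __init__(self, energy, per_item_parameter_names=(), items=(),
                 global_parameters=None):
        pe = energy if isinstance(energy, _expr.ParsedExpression) else _expr.parse(energy)
        self.param_names = list(per_item_parameter_names)
        self.globals = dict(global_parameters or {})
        allowed = {"x", "y", "z"} | set(self.param_names) | set(self.globals)
        unknown = pe.free_variables - allowed
        if unknown:
            raise ValueError(f"expression references unknown variables {sorted(unknown)}")
        order = ["x", "y", "z"] + self.param_names + sorted(self.globals)
        self._fn = _expr.compile_function(pe, order)
        self._dfns = [
            _expr.compile_function(_expr.differentiate(pe, v), order)
            if v in pe.free_variables else None
            for v in ("x", "y", "z")
        ]
        self.atoms = np.array([it[0] for it in items], dtype=int)
        vals = [list(it[1]) for it in items]
        for v in vals:
            if len(v) != len(self.param_names):
                raise ValueError("parameter table width mismatch")
        self.param_values = np.array(vals, dtype=float) if vals else np.zeros((0, 0))

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        if len(self.atoms) == 0:
            return 0.0, forces
        xyz = positions[self.atoms]
        args = [xyz[:, 0], xyz[:, 1], xyz[:, 2]] \
            + [self.param_values[:, i] for i in range(len(self.param_names))] \
            + [self.globals[k] for k in sorted(self.globals)]
        energy = float(np.sum(np.atleast_1d(self._fn(*args))))
        for axis, dfn in enumerate(self._dfns):
            if dfn is not None:
                g = np.atleast_1d(dfn(*args))
                np.add.at(forces[:, axis], self.atoms, -g)
        return energy, forces


class CustomNonbondedTerm:
    """Pair energy expression in ``r`` with per-particle parameters.

    Per-particle parameters are referenced with suffixes 1 and 2 (``sig1``,
    ``sig2``) so combination rules can be written as intermediate
    definitions, e.g. ``"4*eps*((sig/r)^12-(sig/r)^6); sig=0.5*(sig1+sig2);
    eps=sqrt(eps1*eps2)"``.
    """

    category = "Nonbonded"

    def __init__(self, energy, per_particle_parameter_names=(), particle_values=(),
                 global_parameters=None, exclusions=(), cutoff=None, periodic=False):
        pe = energy if isinstance(energy, _expr.ParsedExpression) else _expr.parse(energy)
        self.param_names = list(per_particle_parameter_names)
        self.globals = dict(global_parameters or {})
        self.cutoff = cutoff
        self.periodic = periodic
        suffixed = [f"{p}{s}" for p in self.param_names for s in (1, 2)]
        allowed = {"r"} | set(suffixed) | set(self.globals)
        unknown = pe.free_variables - allowed
        if unknown:
            raise ValueError(f"expression references unknown variables {sorted(unknown)}")
        order = ["r"] + suffixed + sorted(self.globals)
        self._fn = _expr.compile_function(pe, order)
        self._dfn = _expr.compile_function(_expr.differentiate(pe, "r"), order)
        self.values = np.array([list(v) for v in particle_values], dtype=float) \
            if len(particle_values) else np.zeros((0, len(self.param_names)))
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        n = len(self.values)
        skip = {(min(i, j), max(i, j)) for i, j in exclusions}
        ii, jj = np.triu_indices(n, k=1)
        if skip:
            keep = np.array([(int(a), int(b)) not in skip for a, b in zip(ii, jj)])
            ii, jj = ii[keep], jj[keep]
        self.ii, self.jj = ii, jj

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        if len(self.ii) == 0:
            return 0.0, forces
        use_box = box if self.periodic else None
        if self.periodic and self.cutoff is not None and box is not None:
            if self.cutoff > box.inscribed_sphere_diameter() / 2:
                raise ValueError("cutoff exceeds half the box inscribed-sphere diameter")
        dr = minimum_image_many(use_box, positions[self.jj] - positions[self.ii])
        r = np.linalg.norm(dr, axis=1)
        mask = np.ones(len(r), dtype=bool) if self.cutoff is None else (r < self.cutoff)
        ii, jj, dr, r = self.ii[mask], self.jj[mask], dr[mask], r[mask]
        args = [r]
        for p in range(len(self.param_names)):
            args.append(self.values[ii, p])
            args.append(self.values[jj, p])
        args += [self.globals[k] for k in sorted(self.globals)]
        e = np.atleast_1d(self._fn(*args))
        dEdr = np.atleast_1d(self._dfn(*args))
        u = dr / np.maximum(r, 1e-300)[:, None]
        _scatter(forces, ii, dEdr[:, None] * u)
        _scatter(forces, jj, -dEdr[:, None] * u)
        return float(np.sum(e)), forces


class CustomCompoundBondTerm:
    """Energy expression over N named particle slots per item.

    The expression may use ``distance(p1,p2)``, ``angle(p1,p2,p3)``,
    ``dihedral(p1,p2,p3,p4)`` and the slot coordinates ``x1, y1, z1, ...``.
    Forces flow by the chain rule through each geometric primitive.
    """

    category = "Other"
    slot_prefix = "p"

    def __init__(self, energy, n_particles, per_item_parameter_names=(), items=(),
                 global_parameters=None):
        self.n_slots = n_particles
        self.param_names = list(per_item_parameter_names)
        self.globals = dict(global_parameters or {})
        text = energy
        pe = text if isinstance(text, _expr.ParsedExpression) else _parse_compound(text)
        self._geoms, pe = _extract_geometric_calls(pe, self.slot_prefix, self.n_slots)
        coord_vars = sorted(v for v in pe.free_variables
                            if _coord_slot(v, self.n_slots) is not None)
        aux_vars = [g.var for g in self._geoms]
        allowed = set(aux_vars) | set(coord_vars) | set(self.param_names) | set(self.globals)
        unknown = pe.free_variables - allowed
        if unknown:
            raise ValueError(f"expression references unknown variables {sorted(unknown)}")
        self.coord_vars = coord_vars
        order = aux_vars + coord_vars + self.param_names + sorted(self.globals)
        self._fn = _expr.compile_function(pe, order)
        self._dfns = {
            v: _expr.compile_function(_expr.differentiate(pe, v), order)
            for v in aux_vars + coord_vars if v in pe.free_variables
        }
        idx_rows, val_rows = [], []
        for atoms, values in items:
            atoms = list(atoms)
            if len(atoms) != self.n_slots:
                raise ValueError("item particle count mismatch")
            values = list(values)
            if len(values) != len(self.param_names):
                raise ValueError("parameter table width mismatch")
            idx_rows.append(atoms)
            val_rows.append(values)
        self.atom_idx = np.array(idx_rows, dtype=int) if idx_rows \
            else np.zeros((0, self.n_slots), dtype=int)
        self.param_values = np.array(val_rows, dtype=float) if val_rows \
            else np.zeros((0, len(self.param_names)))

    def _slot_positions(self, positions):
        """(n_items, n_slots, 3) slot coordinates; identity for plain atoms."""
        return positions[self.atom_idx]

    def _distribute(self, forces, slot_grads):
        """Scatter per-slot force contributions onto real atoms."""
        for s in range(self.n_slots):
            _scatter(forces, self.atom_idx[:, s], slot_grads[:, s, :])

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        n_items = len(self.atom_idx)
        if n_items == 0:
            return 0.0, forces
        slots = self._slot_positions(positions)  # (items, slots, 3)
        args, geom_grads = [], []
        for g in self._geoms:
            val, grads = g.evaluate(slots)
            args.append(val)
            geom_grads.append(grads)
        coord_cols = []
        for v in self.coord_vars:
            axis, slot = _coord_slot(v, self.n_slots)
            coord_cols.append(slots[:, slot, axis])
        args += coord_cols
        args += [self.param_values[:, i] for i in range(len(self.param_names))]
        args += [self.globals[k] for k in sorted(self.globals)]
        energy = float(np.sum(np.atleast_1d(self._fn(*args))))
        slot_force = np.zeros_like(slots)
        for g, grads in zip(self._geoms, geom_grads):
            dfn = self._dfns.get(g.var)
            if dfn is None:
                continue
            dEdg = np.atleast_1d(dfn(*args))
            for slot, grad in zip(g.slots, grads):
                slot_force[:, slot, :] -= dEdg[:, None] * grad
        for v in self.coord_vars:
            dfn = self._dfns.get(v)
            if dfn is None:
                continue
            axis, slot = _coord_slot(v, self.n_slots)
            slot_force[:, slot, axis] -= np.atleast_1d(dfn(*args))
        self._distribute(forces, slot_force)
        return energy, forces


class CustomCentroidBondTerm(CustomCompoundBondTerm):
    """Compound-bond expression evaluated on weighted group centroids.

    Slots are centroids of atom groups (weights default to masses,
    normalized); the force on each centroid is shared among the group's
    members in proportion to their normalized weights.
    """

    slot_prefix = "g"

    def __init__(self, energy, groups, per_item_parameter_names=(), items=(),
                 global_parameters=None, masses=None):
        self.groups = []
        for g in groups:
            if isinstance(g, tuple) and len(g) == 2 and not np.isscalar(g[0]):
                idx, wts = g
            else:
                idx, wts = g, None
            idx = np.asarray(idx, dtype=int)
            if wts is None:
                if masses is None:
                    raise ValueError("weights omitted and no masses supplied")
                wts = np.asarray(masses, dtype=float)[idx]
            wts = np.asarray(wts, dtype=float)
            total = wts.sum()
            if total <= 0:
                raise ValueError("group weights must sum to a positive value")
            self.groups.append((idx, wts / total))
        super().__init__(energy, len(self.groups), per_item_parameter_names,
                         items, global_parameters)

    def energy_and_forces(self, positions, box=None):
        forces = np.zeros_like(positions)
        n_items = len(self.atom_idx)
        if n_items == 0:
            return 0.0, forces
        centroids = np.array([
            np.sum(positions[idx] * w[:, None], axis=0) for idx, w in self.groups
        ])
        slots = centroids[self.atom_idx]  # atom_idx here indexes groups
        args, geom_grads = [], []
        for g in self._geoms:
            val, grads = g.evaluate(slots)
            args.append(val)
            geom_grads.append(grads)
        coord_cols = []
        for v in self.coord_vars:
            axis, slot = _coord_slot(v, self.n_slots)
            coord_cols.append(slots[:, slot, axis])
        args += coord_cols
        args += [self.param_values[:, i] for i in range(len(self.param_names))]
        args += [self.globals[k] for k in sorted(self.globals)]
        energy = float(np.sum(np.atleast_1d(self._fn(*args))))
        slot_force = np.zeros_like(slots)
        for g, grads in zip(self._geoms, geom_grads):
            dfn = self._dfns.get(g.var)
            if dfn is None:
                continue
            dEdg = np.atleast_1d(dfn(*args))
            for slot, grad in zip(g.slots, grads):
                slot_force[:, slot, :] -= dEdg[:, None] * grad
        for v in self.coord_vars:
            dfn = self._dfns.get(v)
            if dfn is None:
                continue
            axis, slot = _coord_slot(v, self.n_slots)
            slot_force[:, slot, axis] -= np.atleast_1d(dfn(*args))
        # distribute centroid forces to group members by normalized weight
        for item in range(n_items):
            for s in range(self.n_slots):
                gi = self.atom_idx[item, s]
                idx, w = self.groups[gi]
                forces[idx] += w[:, None] * slot_force[item, s]
        return energy, forces


# -- compound-expression plumbing -------------------------------------------

class _GeomCall:
    """One distance/angle/dihedral call lifted out of a compound expression."""

    def __init__(self, kind, slots, var):
        self.kind = kind
        self.slots = slots  # 0-based slot indices
        self.var = var

    def evaluate(self, slots):
        """Value per item and gradient arrays per involved slot."""
        p = [slots[:, s, :] for s in self.slots]
        if self.kind == "distance":
            dr = p[1] - p[0]
            r = np.linalg.norm(dr, axis=1)
            u = dr / np.maximum(r, 1e-300)[:, None]
            return r, [-u, u]
        if self.kind == "angle":
            u = p[0] - p[1]
            w = p[2] - p[1]
            lu = np.linalg.norm(u, axis=1)
            lw = np.linalg.norm(w, axis=1)
            uh, wh = u / lu[:, None], w / lw[:, None]
            cos_t = np.clip(np.einsum("nd,nd->n", uh, wh), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.maximum(np.sqrt(1.0 - cos_t**2), _MIN_SIN)
            di = (cos_t[:, None] * uh - wh) / (lu * sin_t)[:, None]
            dk = (cos_t[:, None] * wh - uh) / (lw * sin_t)[:, None]
            return theta, [di, -(di + dk), dk]
        if self.kind == "dihedral":
            b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
            n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
            lb2 = np.linalg.norm(b2, axis=1)
            y = np.einsum("nd,nd->n", np.cross(n1, n2), b2 / lb2[:, None])
            x = np.einsum("nd,nd->n", n1, n2)
            phi = np.arctan2(y, x)
            n1sq = np.maximum(np.einsum("nd,nd->n", n1, n1), 1e-300)
            n2sq = np.maximum(np.einsum("nd,nd->n", n2, n2), 1e-300)
            di = -(lb2 / n1sq)[:, None] * n1
            dl = (lb2 / n2sq)[:, None] * n2
            d12 = np.einsum("nd,nd->n", b1, b2) / lb2**2
            d32 = np.einsum("nd,nd->n", b3, b2) / lb2**2
            dj = -(1.0 + d12)[:, None] * di + d32[:, None] * dl
            dk = d12[:, None] * di - (1.0 + d32)[:, None] * dl
            return phi, [di, dj, dk, dl]
        raise AssertionError(self.kind)


_GEOM_ARITY = {"distance": 2, "angle": 3, "dihedral": 4}


def _parse_compound(text: str) -> _expr.ParsedExpression:
    """Parse with distance/angle/dihedral temporarily in the function table."""
    saved = dict(_expr.FUNCTIONS)
    try:
        _expr.FUNCTIONS.update(_GEOM_ARITY)
        return _expr.parse(text)
    finally:
        _expr.FUNCTIONS.clear()
        _expr.FUNCTIONS.update(saved)


def _coord_slot(name: str, n_slots: int):
    """Map 'x3' -> (axis 0, slot 2) etc.; None if not a coordinate variable."""
    if len(name) >= 2 and name[0] in "xyz" and name[1:].isdigit():
        slot = int(name[1:]) - 1
        if 0 <= slot < n_slots:
            return "xyz".index(name[0]), slot
    return None


def _extract_geometric_calls(pe: _expr.ParsedExpression, prefix: str, n_slots: int):
    """Replace distance/angle/dihedral calls by fresh aux variables."""
    geoms: list[_GeomCall] = []
    cache: dict[tuple, str] = {}

    def slot_of(node: _expr.ExprNode) -> int:
        if node.kind != "variable" or not node.name.startswith(prefix) \
                or not node.name[len(prefix):].isdigit():
            raise ValueError(
                f"geometric call arguments must be slot names like {prefix}1"
            )
        s = int(node.name[len(prefix):]) - 1
        if not 0 <= s < n_slots:
            raise ValueError(f"particle slot index out of range: {node.name}")
        return s

    def walk(node: _expr.ExprNode) -> _expr.ExprNode:
        if node.kind == "call" and node.name in _GEOM_ARITY:
            slots = tuple(slot_of(c) for c in node.children)
            key = (node.name, slots)
            if key not in cache:
                var = f"_geom{len(geoms)}"
                cache[key] = var
                geoms.append(_GeomCall(node.name, slots, var))
            return _expr.ExprNode("variable", name=cache[key])
        if not node.children:
            return node
        return _expr.ExprNode(node.kind, value=node.value, name=node.name,
                              children=tuple(walk(c) for c in node.children))

    root = walk(pe.root)
    defs = [(n, walk(d)) for n, d in pe.definitions]
    return geoms, _expr.ParsedExpression(root, defs, set(pe.parameters))
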