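"""Generalized three-parent virtual sites.

A virtual site is a massless interaction site whose position is a
deterministic function of three parent atoms.  A local frame is built from
weighted averages of the parent positions

    o  = w1o*r1 + w2o*r2 + w3o*r3        (origin; weights sum to 1)
    dx = w1x*r1 + w2x*r2 + w3x*r3        (weights sum to 0)
    dy = w1y*r1 + w2y*r2 + w3y*r3        (weights sum to 0)

orthonormalized as dz = dx x dy, xhat = dx/|dx|, zhat = dz/|dz|,
yhat = zhat x xhat, and the site sits at a fixed local offset

    r_site = o + p1*xhat + p2*yhat + p3*zhat.

Because the axis weights sum to zero the frame is translation invariant, and
because it rotates rigidly with the parents the rule is equivariant under
rigid motions.  Forces applied to the site are redistributed onto the parents
with the exact transpose Jacobian of the position rule, which preserves the
net force and the net torque.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ThreeParticleSite", "compute_site_position", "distribute_site_force",
           "update_all_sites"]

_DEGENERACY_TOL = 1e-10


@dataclass(frozen=True)
class ThreeParticleSite:
    """Definition of one generalized three-parent virtual site."""

    site: int
    parents: tuple[int, int, int]
    origin_weights: tuple[float, float, float]
    x_weights: tuple[float, float, float]
    y_weights: tuple[float, float, float]
    local_position: tuple[float, float, float]

    def __post_init__(self):
        if abs(sum(self.origin_weights) - 1.0) > 1e-10:
            raise ValueError("origin weights must sum to 1 (affine combination)")
        if abs(sum(self.x_weights)) > 1e-10 or abs(sum(self.y_weights)) > 1e-10:
            raise ValueError("axis weights must sum to 0 (translation invariance)")
        if len(set(self.parents)) != 3:
            raise ValueError("parents must be three distinct atoms")


def _frame(site: ThreeParticleSite, r1, r2, r3):
    rs = (np.asarray(r1, float), np.asarray(r2, float), np.asarray(r3, float))
    o = sum(w * r for w, r in zip(site.origin_weights, rs))
    dx = sum(w * r for w, r in zip(site.x_weights, rs))
    dy = sum(w * r for w, r in zip(site.y_weights, rs))
    ndx = np.linalg.norm(dx)
    dz = np.cross(dx, dy)
    ndz = np.linalg.norm(dz)
    if ndx < _DEGENERACY_TOL or ndz < _DEGENERACY_TOL:
        raise ValueError("degenerate virtual-site geometry (dx zero or dx || dy)")
    xhat = dx / ndx
    zhat = dz / ndz
    yhat = np.cross(zhat, xhat)
    return o, dx, dy, dz, ndx, ndz, xhat, yhat, zhat


def compute_site_position(site: ThreeParticleSite, r1, r2, r3) -> np.ndarray:
    """Position of the virtual site given its three parent positions (nm)."""
    o, _, _, _, _, _, xhat, yhat, zhat = _frame(site, r1, r2, r3)
    p1, p2, p3 = site.local_position
    return o + p1 * xhat + p2 * yhat + p3 * zhat


def _cross_matrix(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def site_jacobians(site: ThreeParticleSite, r1, r2, r3) -> list[np.ndarray]:
    """Analytic Jacobians d(r_site)/d(r_k) for the three parents (3x3 each)."""
    o, dx, dy, dz, ndx, ndz, xhat, yhat, zhat = _frame(site, r1, r2, r3)
    p1, p2, p3 = site.local_position
    eye = np.eye(3)
    proj_x = (eye - np.outer(xhat, xhat)) / ndx     # d xhat / d dx
    proj_z = (eye - np.outer(zhat, zhat)) / ndz     # d zhat / d dz
    dz_ddx = -_cross_matrix(dy)                      # d (dx x dy) / d dx
    dz_ddy = _cross_matrix(dx)
    zhat_ddx = proj_z @ dz_ddx
    zhat_ddy = proj_z @ dz_ddy
    # yhat = zhat x xhat  =>  d yhat = -[xhat]_x d zhat + [zhat]_x d xhat
    yhat_ddx = -_cross_matrix(xhat) @ zhat_ddx + _cross_matrix(zhat) @ proj_x
    yhat_ddy = -_cross_matrix(xhat) @ zhat_ddy
    jacs = []
    for wo, wx, wy in zip(site.origin_weights, site.x_weights, site.y_weights):
        J = wo * eye
        J = J + p1 * proj_x * wx
        J = J + p2 * (yhat_ddx * wx + yhat_ddy * wy)
        J = J + p3 * (zhat_ddx * wx + zhat_ddy * wy)
        jacs.append(J)
    return jacs


def distribute_site_force(site: ThreeParticleSite, r1, r2, r3, f_site):
    """Redistribute a force on the site onto the parents: f_k = J_k^T f.

    The Jacobians sum to the identity (origin weights sum to 1, axis weights
    to 0), so the parent forces sum exactly to ``f_site``.
    """
    f_site = np.asarray(f_site, dtype=float)
    jacs = site_jacobians(site, r1, r2, r3)
    return tuple(J.T @ f_site for J in jacs)


def update_all_sites(system, positions: np.ndarray) -> np.ndarray:
    """Overwrite every virtual-site position from its parents.

    Must run after any operation that changes positions and before any force
    evaluation.  Idempotent: parents are never virtual.
    """
    if not system.virtual_sites:
        return positions
    pos = np.array(positions, dtype=float)
    for idx, site in system.virtual_sites.items():
        i1, i2, i3 = site.parents
        pos[idx] = compute_site_position(site, pos[i1], pos[i2], pos[i3])
    return pos


def apply_site_forces(system, positions: np.ndarray, forces: np.ndarray) -> np.ndarray:
    """Move force accumulated on virtual sites onto their parent atoms."""
    if not system.virtual_sites:
        return forces
    f = np.array(forces, dtype=float)
    for idx, site in system.virtual_sites.items():
        i1, i2, i3 = site.parents
        f1, f2, f3 = distribute_site_force(
            site, positions[i1], positions[i2], positions[i3], f[idx]
        )
        f[i1] += f1
        f[i2] += f2
        f[i3] += f3
        f[idx] = 0.0
    return f
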