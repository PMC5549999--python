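"""Triclinic periodic boxes, standard box shapes, minimum image, wrapping.

A periodic cell is spanned by three lattice vectors.  We keep every box in a
*reduced* form — ``a`` along x, ``b`` in the xy plane, and off-diagonal
components at most half the corresponding diagonal — which guarantees the
minimum-image search can be restricted to the 27 neighbouring cells.  The
rhombic dodecahedron and truncated octahedron are represented as triclinic
cells; at equal minimum image distance they have about 71% and 77% of the
volume of a cube, which is why they are popular for freely rotating solutes.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

__all__ = [
    "TriclinicBox",
    "reduce_box",
    "box_from_geometry",
    "minimum_image",
    "minimum_image_many",
    "wrap_positions",
]

_SQ2 = np.sqrt(2.0)


@dataclass(frozen=True)
class TriclinicBox:
    """Reduced triclinic cell: a=(ax,0,0), b=(bx,by,0), c=(cx,cy,cz)."""

    a: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        b = np.asarray(self.b, dtype=float)
        c = np.asarray(self.c, dtype=float)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)
        eps = 1e-9
        if not (a[1] == 0 and a[2] == 0 and b[2] == 0):
            raise ValueError("box not in reduced form (a along x, b in xy plane)")
        if not (a[0] > 0 and b[1] > 0 and c[2] > 0):
            raise ValueError("box diagonal must be positive")
        if abs(b[0]) > a[0] / 2 + eps or abs(c[0]) > a[0] / 2 + eps or abs(c[1]) > b[1] / 2 + eps:
            raise ValueError("off-diagonal box components exceed half-diagonal bounds")

    @property
    def matrix(self) -> np.ndarray:
        """Lattice vectors as rows."""
        return np.array([self.a, self.b, self.c])

    @property
    def volume(self) -> float:
        return float(self.a[0] * self.b[1] * self.c[2])

    def inscribed_sphere_diameter(self) -> float:
        """Twice the distance from the cell center to the nearest face pair."""
        m = self.matrix
        widths = []
        for i, j, k in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
            n = np.cross(m[j], m[k])
            widths.append(abs(np.dot(m[i], n)) / np.linalg.norm(n))
        return float(min(widths))


def reduce_box(a, b, c) -> TriclinicBox:
    """Canonicalize arbitrary lattice vectors to reduced triclinic form.

    The cell is rotated so ``a`` lies along x and ``b`` in the xy plane, then
    lattice-reduced (subtracting integer multiples of earlier vectors) so the
    off-diagonal components obey the half-diagonal bounds.  The generated
    periodic lattice and the cell volume are unchanged.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    c = np.asarray(c, dtype=float)
    vol = np.dot(a, np.cross(b, c))
    if abs(vol) < 1e-12:
        raise ValueError("degenerate (coplanar) lattice vectors")
    # rotate into the canonical frame using lengths and mutual angles
    la = np.linalg.norm(a)
    ahat = a / la
    bx = np.dot(b, ahat)
    by = np.sqrt(np.dot(b, b) - bx * bx)
    if by < 1e-12:
        raise ValueError("degenerate lattice: b parallel to a")
    cx = np.dot(c, ahat)
    cy = (np.dot(b, c) - bx * cx) / by
    cz2 = np.dot(c, c) - cx * cx - cy * cy
    if cz2 <= 1e-24:
        raise ValueError("degenerate lattice: c in the plane of a and b")
    cz = np.sqrt(cz2)
    if vol < 0:
        # axis alignment flips handedness; require positive triple product
        raise ValueError("lattice vectors must form a right-handed set")
    ra = np.array([la, 0.0, 0.0])
    rb = np.array([bx, by, 0.0])
    rc = np.array([cx, cy, cz])
    # lattice reduction (order matters: c against b, then c and b against a)
    rc -= rb * np.round(rc[1] / rb[1])
    rc -= ra * np.round(rc[0] / ra[0])
    rb -= ra * np.round(rb[0] / ra[0])
    return TriclinicBox(ra, rb, rc)


def box_from_geometry(kind: str, width: float) -> TriclinicBox:
    """Standard periodic cell with minimum image distance ``width``.

    ``kind`` is ``cube``, ``rhombic_dodecahedron`` or ``truncated_octahedron``.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    w = float(width)
    if kind == "cube":
        return TriclinicBox((w, 0, 0), (0, w, 0), (0, 0, w))
    if kind == "rhombic_dodecahedron":
        # square-in-xy representation; volume w^3/sqrt(2)
        return TriclinicBox((w, 0, 0), (0, w, 0), (w / 2, w / 2, w * _SQ2 / 2))
    if kind == "truncated_octahedron":
        # volume (4*sqrt(3)/9) w^3
        return TriclinicBox(
            (w, 0, 0),
            (w / 3, 2 * _SQ2 * w / 3, 0),
            (-w / 3, _SQ2 * w / 3, np.sqrt(6.0) * w / 3),
        )
    raise ValueError(f"unknown box kind {kind!r}")


def minimum_image(box: TriclinicBox, dr) -> np.ndarray:
    """Displacement to the nearest periodic image of ``dr``.

    Returns ``dr + i*a + j*b + k*c`` with the smallest Euclidean norm; exact
    ties are broken by the lexicographically smallest ``(i, j, k)``.
    """
    out, _ = _minimum_image_indexed(box, np.asarray(dr, dtype=float))
    return out


def _minimum_image_indexed(box: TriclinicBox, dr: np.ndarray):
    a, b, c = box.a, box.b, box.c
    # coarse shift toward the origin gives an upper bound on the minimum norm
    k0 = -np.round(dr[2] / c[2])
    v = dr + k0 * c
    j0 = -np.round(v[1] / b[1])
    v = v + j0 * b
    i0 = -np.round(v[0] / a[0])
    v = v + i0 * a
    bound = float(np.linalg.norm(v)) + 1e-12
    # exact search: the reduced form is triangular (a_z = b_z = 0), so the
    # index ranges that can still beat the bound are computable per axis
    best = None
    k_span = int(np.floor((bound + abs(v[2])) / c[2])) + 1
    for dk in range(-k_span, k_span + 1):
        vz = v[2] + dk * c[2]
        if abs(vz) > bound:
            continue
        vy0 = v[1] + dk * c[1]
        j_span = int(np.floor((bound + abs(vy0)) / b[1])) + 1
        for dj in range(-j_span, j_span + 1):
            vy = vy0 + dj * b[1]
            if vz * vz + vy * vy > bound * bound:
                continue
            vx0 = v[0] + dk * c[0] + dj * b[0]
            i_span = int(np.floor((bound + abs(vx0)) / a[0])) + 1
            for di in range(-i_span, i_span + 1):
                vx = vx0 + di * a[0]
                n2 = vx * vx + vy * vy + vz * vz
                idx = (int(i0) + di, int(j0) + dj, int(k0) + dk)
                key = (n2, idx)
                if best is None or _tie_lt(key, best[0]):
                    best = (key, np.array([vx, vy, vz]))
    return best[1], best[0][1]


def _tie_lt(key_a, key_b, tol=1e-12):
    na, ia = key_a
    nb, ib = key_b
    if na < nb - tol:
        return True
    if na > nb + tol:
        return False
    return ia < ib


def minimum_image_many(box: TriclinicBox | None, dr: np.ndarray) -> np.ndarray:
    """Vectorized minimum image for an (n, 3) array of displacements.

    ``box=None`` means non-periodic (identity).  Uses the coarse fractional
    shift plus a 27-candidate search, valid for reduced boxes.
    """
    dr = np.asarray(dr, dtype=float)
    if box is None:
        return dr
    a, b, c = box.a, box.b, box.c
    v = dr - np.outer(np.round(dr[:, 2] / c[2]), c)
    v -= np.outer(np.round(v[:, 1] / b[1]), b)
    v -= np.outer(np.round(v[:, 0] / a[0]), a)
    shifts = np.array([di * a + dj * b + dk * c
                       for di, dj, dk in product((-1, 0, 1), repeat=3)])
    cand = v[:, None, :] + shifts[None, :, :]  # (n, 27, 3)
    n2 = np.einsum("nkd,nkd->nk", cand, cand)
    pick = np.argmin(n2, axis=1)
    return cand[np.arange(len(dr)), pick]


def wrap_positions(box: TriclinicBox, positions, molecule_groups) -> np.ndarray:
    """Translate each molecule by lattice vectors so its centroid lies in the
    primary cell; intra-molecular geometry is untouched."""
    pos = np.array(positions, dtype=float)
    inv = np.linalg.inv(box.matrix.T)
    for group in molecule_groups:
        idx = np.asarray(group, dtype=int)
        centroid = pos[idx].mean(axis=0)
        frac = inv @ centroid
        shift = -np.floor(frac)
        if np.any(shift != 0):
            pos[idx] += box.matrix.T @ shift
    return pos
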