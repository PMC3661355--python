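"""Exact vector geometry for internal-coordinate model building.

Measurement (distance, planar angle, torsion), single-atom placement from
internal coordinates (NeRF-style: three reference atoms plus a bond length,
a planar angle and a dihedral), and least-squares rigid superposition.

Conventions
-----------
* All angles are in degrees at the API surface; radians are internal only.
* Torsions follow the IUPAC sign convention: looking from ``b`` toward
  ``c``, a clockwise rotation of the far bond ``c->d`` relative to the
  near bond ``b->a`` is positive.  cis = 0, trans = +180; the returned
  range is (-180, 180].
* Coordinates are ``numpy`` arrays of shape (3,), in Angstroms.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "vec3",
    "distance",
    "bond_angle",
    "dihedral_angle",
    "place_atom",
    "kabsch_superpose",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised for degenerate geometric input (coincident or collinear atoms)."""


def vec3(x: float, y: float, z: float) -> np.ndarray:
    """Return a finite 3-vector (Angstroms) as a float64 array."""
    v = np.array([x, y, z], dtype=float)
    if not np.all(np.isfinite(v)):
        raise GeometryError(f"non-finite coordinate: {v}")
    return v


def _as_vec(p) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    if v.shape != (3,):
        raise GeometryError(f"expected a 3-vector, got shape {v.shape}")
    return v


def distance(p, q) -> float:
    """Euclidean distance |p - q| in Angstroms."""
    return float(np.linalg.norm(_as_vec(p) - _as_vec(q)))


def bond_angle(a, b, c) -> float:
    """Planar angle at vertex ``b`` between rays b->a and b->c, in [0, 180] degrees."""
    u = _as_vec(a) - _as_vec(b)
    v = _as_vec(c) - _as_vec(b)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise GeometryError("bond_angle: coincident atoms (zero-length ray)")
    cosang = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))


def dihedral_angle(a, b, c, d) -> float:
    """Signed torsion a-b-c-d about the b->c axis, in (-180, 180] degrees.

    Uses the two-argument arctangent formulation, which is numerically
    stable near 0 and 180.
    """
    a, b, c, d = (_as_vec(p) for p in (a, b, c, d))
    b0 = a - b
    b1 = c - b
    b2 = d - c
    n1 = np.linalg.norm(b1)
    if n1 == 0.0:
        raise GeometryError("dihedral_angle: axis atoms b and c coincide")
    b1 = b1 / n1
    # components of b0/b2 perpendicular to the axis
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    if np.linalg.norm(v) < 1e-10 or np.linalg.norm(w) < 1e-10:
        raise GeometryError("dihedral_angle: collinear reference triple")
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0:
        ang += 360.0
    return ang


def place_atom(a, b, c, bond_length: float, angle: float, dihedral: float) -> np.ndarray:
    """Position a new atom D from three placed reference atoms.

    The returned point satisfies ``distance(c, D) == bond_length``,
    ``bond_angle(b, c, D) == angle`` and
    ``dihedral_angle(a, b, c, D) == dihedral`` (each to ~1e-6).

    Parameters
    ----------
    a, b, c
        Previously placed reference atoms; must not be collinear.
    bond_length
        c-D distance in Angstroms, > 0.
    angle
        Planar angle b-c-D in degrees, in (0, 180).
    dihedral
        Torsion a-b-c-D in degrees (IUPAC sign).
    """
    if bond_length <= 0.0:
        raise GeometryError(f"place_atom: bond_length must be > 0, got {bond_length}")
    if not 0.0 < angle < 180.0:
        raise GeometryError(f"place_atom: angle must be in (0, 180), got {angle}")
    a, b, c = (_as_vec(p) for p in (a, b, c))

    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc == 0.0:
        raise GeometryError("place_atom: reference atoms b and c coincide")
    e_bc = bc / nbc
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise GeometryError("place_atom: collinear reference atoms a, b, c")
    n = n / nn  # normal of the a-b-c plane
    m = np.cross(n, e_bc)  # in-plane, perpendicular to bc, pointing to the a side

    theta = np.radians(angle)
    chi = np.radians(dihedral)
    # local frame at c: e_bc (along axis), m (dihedral zero direction), n
    d_local = (
        -np.cos(theta) * e_bc
        + np.sin(theta) * (np.cos(chi) * m + np.sin(chi) * n)
    )
    return c + bond_length * d_local


def kabsch_superpose(moving, fixed):
    """Optimal rigid superposition of ``moving`` onto ``fixed`` (Kabsch).

    Parameters
    ----------
    moving, fixed
        Sequences of 3-vectors of equal length n >= 3.

    Returns
    -------
    rotation : (3, 3) ndarray
        Proper rotation matrix (det = +1).
    translation : (3,) ndarray
        Offset such that ``moving @ rotation.T + translation`` best fits
        ``fixed`` in the least-squares sense.
    rmsd : float
        Root-mean-square deviation after superposition, in Angstroms.
    """
    mv = np.atleast_2d(np.asarray(moving, dtype=float))
    fx = np.atleast_2d(np.asarray(fixed, dtype=float))
    if mv.shape != fx.shape:
        raise GeometryError(
            f"kabsch_superpose: point sets differ in shape {mv.shape} vs {fx.shape}"
        )
    if mv.ndim != 2 or mv.shape[1] != 3 or mv.shape[0] < 3:
        raise GeometryError("kabsch_superpose: need n >= 3 points of dimension 3")
    cm = mv.mean(axis=0)
    cf = fx.mean(axis=0)
    rot, rssd = Rotation.align_vectors(fx - cf, mv - cm)
    rmat = rot.as_matrix()
    translation = cf - rmat @ cm
    rmsd = float(rssd) / np.sqrt(mv.shape[0])
    return rmat, translation, rmsd
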