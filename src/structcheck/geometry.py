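"""Geometric primitives: signed dihedral angles and internal-to-Cartesian
atom placement.

The dihedral sign follows the IUPAC convention: looking down the p2->p3
axis, a clockwise rotation carrying the p1 projection onto the p4
projection is positive.  Angles are reported in degrees in (-180, 180],
with the trans value mapped to +180.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

#: Norm below which an intermediate cross product is considered degenerate.
DEGENERACY_TOL = 1e-10


def _cross(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # 3-vector cross product; avoids np.cross dispatch overhead in hot loops
    return np.array([a[1] * b[2] - a[2] * b[1],
                     a[2] * b[0] - a[0] * b[2],
                     a[0] * b[1] - a[1] * b[0]])


def dihedral(p1, p2, p3, p4) -> float:
    """Signed torsion angle p1-p2-p3-p4 in degrees, in (-180, 180].

    Raises
    ------
    DegenerateGeometryError
        If p2 == p3 or either bonded triple is collinear.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if nb2 < DEGENERACY_TOL:
        raise DegenerateGeometryError("degenerate dihedral: p2 and p3 coincide")
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    if np.linalg.norm(n1) < DEGENERACY_TOL or np.linalg.norm(n2) < DEGENERACY_TOL:
        raise DegenerateGeometryError("degenerate dihedral: collinear triple")
    x = float(np.dot(n1, n2))
    y = float(np.dot(_cross(n1, n2), b2 / nb2))
    ang = float(np.degrees(np.arctan2(y, x)))
    if ang <= -180.0 + 1e-12:
        ang = 180.0
    return ang


def bond_angle(p1, p2, p3) -> float:
    """Angle p1-p2-p3 in degrees, in [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    v1 = p1 - p2
    v2 = p3 - p2
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < DEGENERACY_TOL or n2 < DEGENERACY_TOL:
        raise DegenerateGeometryError("degenerate angle: coincident points")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def place_atom(a, b, c, bond_length: float, angle_deg: float,
               torsion_deg: float) -> np.ndarray:
    """Place atom D from three reference atoms by internal coordinates (NeRF).

    D is bonded to ``c`` at ``bond_length``, with bond angle b-c-D equal to
    ``angle_deg`` and torsion a-b-c-D equal to ``torsion_deg`` under the same
    sign convention as :func:`dihedral`.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    # local displacement in the frame where bc is x and the abc plane is xy
    d_local = bond_length * np.array([
        -np.cos(theta),
        np.sin(theta) * np.cos(chi),
        np.sin(theta) * np.sin(chi),
    ])
    bc = c - b
    nbc = np.linalg.norm(bc)
    if nbc < DEGENERACY_TOL:
        raise DegenerateGeometryError("degenerate placement: b and c coincide")
    x = bc / nbc
    ab = b - a
    n = _cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < DEGENERACY_TOL:
        raise DegenerateGeometryError("degenerate placement: a, b, c collinear")
    z = n / nn
    y = _cross(z, x)
    frame = np.column_stack([x, y, z])
    return c + frame @ d_local
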