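"""Torsion-angle geometry: dihedral measurement and internal-coordinate placement.

All angles are in degrees and normalized to the half-open interval
(-180, +180].  The dihedral sign follows the IUPAC convention: looking
down the central bond from the second to the third atom, a clockwise
rotation of the far bond relative to the near bond is positive.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "normalize_angle",
    "signed_arc",
    "dihedral_angle",
    "place_atom",
]

#: Two bond vectors closer to parallel than this (in terms of the norm of
#: their cross product relative to their lengths) are treated as collinear.
_COLLINEAR_TOL = 1e-10


def normalize_angle(angle: float) -> float:
    """Map *angle* (degrees) into (-180, +180]."""
    a = float(angle) % 360.0
    if a > 180.0:
        a -= 360.0
    elif a <= -180.0:  # defensive; fmod of negatives
        a += 360.0
    return a


def signed_arc(start: float, end: float) -> float:
    """Minimal signed rotation (degrees) carrying *start* onto *end*.

    The result lies in (-180, +180]; a displacement of exactly half a turn
    is reported as +180.
    """
    d = (float(end) - float(start)) % 360.0
    if d > 180.0:
        d -= 360.0
    return d


def dihedral_angle(p1, p2, p3, p4) -> float | None:
    """Torsion angle defined by four points, in degrees in (-180, +180].

    Returns ``None`` when the geometry is degenerate (coincident
    consecutive points or collinear bond vectors at the central bond),
    rather than raising: an undefined torsion is an expected condition in
    malformed structures.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    nb2 = np.linalg.norm(b2)
    if (
        np.linalg.norm(b1) < _COLLINEAR_TOL
        or nb2 < _COLLINEAR_TOL
        or np.linalg.norm(b3) < _COLLINEAR_TOL
    ):
        return None
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if (
        np.linalg.norm(n1) < _COLLINEAR_TOL * np.linalg.norm(b1) * nb2
        or np.linalg.norm(n2) < _COLLINEAR_TOL * nb2 * np.linalg.norm(b3)
    ):
        return None
    # atan2 form is numerically stable near 0 and 180 degrees
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2) / nb2
    return normalize_angle(np.degrees(np.arctan2(y, x)))


def place_atom(a, b, c, bond_length: float, bond_angle: float, torsion: float) -> np.ndarray:
    """Place a fourth point D from three reference points by internal coordinates.

    D is at distance *bond_length* from ``c``, forming the angle
    *bond_angle* (degrees) at ``c`` with ``b``, and the torsion
    ``dihedral_angle(a, b, c, D) == torsion`` (degrees).  This is the
    standard natural-extension (NeRF) construction used by chain builders.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(bond_angle)
    chi = np.radians(torsion)
    d_local = bond_length * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    bc = c - b
    bc_hat = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc_hat)
    n_norm = np.linalg.norm(n)
    if n_norm < _COLLINEAR_TOL:
        raise ValueError("reference points a, b, c are collinear; torsion frame undefined")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)
    frame = np.column_stack([bc_hat, m_hat, n_hat])
    return c + frame @ d_local
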