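"""Low-level angular and Cartesian geometry helpers.

Angles are handled in degrees throughout the public API; trigonometry is
performed in radians internally.  All wrapped angles live on the half-open
interval [-180, 180).
"""

from __future__ import annotations

import numpy as np

__all__ = ["wrap_angle", "angular_distance", "dihedral", "place_atom"]


def wrap_angle(angle):
    """Wrap an angle (or array of angles) in degrees onto [-180, 180)."""
    return np.mod(np.asarray(angle, dtype=float) + 180.0, 360.0) - 180.0


def angular_distance(a, b):
    """Minimum-image separation |a - b| on the circle, in degrees (<= 180)."""
    return np.abs(wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))


def dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle of four points, degrees in [-180, 180).

    Uses the atan2 formulation, which is numerically stable near 0 and 180
    degrees.  The sign follows the IUPAC convention: looking down the
    p1->p2 axis, a clockwise rotation of p3 relative to p0 is positive.
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1n = b1 / np.linalg.norm(b1)
    # components of b0/b2 perpendicular to the central bond
    v = b0 - np.dot(b0, b1n) * b1n
    w = b2 - np.dot(b2, b1n) * b1n
    x = np.dot(v, w)
    y = np.dot(np.cross(b1n, v), w)
    return float(wrap_angle(np.degrees(np.arctan2(y, x))))


def place_atom(a, b, c, bond: float, angle: float, torsion: float) -> np.ndarray:
    """Place a new atom D given three positioned atoms A, B, C.

    D is at distance ``bond`` from C, with angle B-C-D equal to ``angle``
    (degrees) and dihedral A-B-C-D equal to ``torsion`` (degrees).  This is
    the standard natural-extension (NeRF) construction used by z-matrix
    builders.
    """
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle)
    phi = np.radians(torsion)
    # local displacement in the frame where C sits at the origin and the
    # B->C direction is +x
    d_local = np.array(
        [
            -bond * np.cos(theta),
            bond * np.sin(theta) * np.cos(phi),
            bond * np.sin(theta) * np.sin(phi),
        ]
    )
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-12:
        raise ValueError("reference atoms A, B, C are collinear")
    n /= norm
    m = np.cross(n, bc)
    rot = np.column_stack([bc, m, n])
    return c + rot @ d_local
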