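"""Geometric primitives: dihedrals, internal-coordinate placement, periodic distances.

All coordinates are Cartesian angstroms. Torsion angles follow the IUPAC sign
convention: the cis (eclipsed) arrangement is 0 deg and the sign is given by the
right-hand rule looking along the p2 -> p3 bond. Angles are reported in the
half-open range (-180, +180].
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "measure_dihedral",
    "measure_angle",
    "nerf_place",
    "rotation_about_axis",
    "minimum_image_displacement",
    "minimum_image_distance",
    "wrap_range",
    "DegenerateGeometryError",
]


class DegenerateGeometryError(ValueError):
    """Raised when a geometric measurement is undefined (coincident/collinear points)."""


def wrap_range(angle_deg):
    """Map an angle in degrees into (-180, +180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    # the formula above maps +180 -> +180 and -180 -> +180
    return wrapped if wrapped.ndim else float(wrapped)


def measure_dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, range (-180, +180].

    Uses the atan2 form, which is numerically stable near 0 and 180 deg.
    Raises :class:`DegenerateGeometryError` for coincident consecutive points or
    collinear triples, where the torsion is undefined.
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    for b in (b1, b2, b3):
        if np.linalg.norm(b) < 1e-10:
            raise DegenerateGeometryError("consecutive points coincide; torsion undefined")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise DegenerateGeometryError("collinear triple; torsion undefined")
    b2n = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2n))
    return wrap_range(np.degrees(np.arctan2(y, x)))


def measure_angle(p1, p2, p3) -> float:
    """Bond angle p1-p2-p3 in degrees, range [0, 180]."""
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p1 - p2
    v = p3 - p2
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-10 or nv < 1e-10:
        raise DegenerateGeometryError("coincident points; angle undefined")
    c = np.clip(np.dot(u, v) / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def nerf_place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom X so that |X-c| = bond, angle(X,c,b) = angle and torsion
    X-c-b-a = dihedral (natural-extension reference frame construction)."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise DegenerateGeometryError("reference atoms collinear; frame undefined")
    n /= nn
    m = np.cross(n, bc)
    # local displacement in the (bc, m, n) frame
    d = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(chi), np.sin(theta) * np.sin(chi)]
    )
    return c + d[0] * bc + d[1] * m + d[2] * n


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis`` (Rodrigues)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    t = np.radians(angle_deg)
    K = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def minimum_image_displacement(a, b, edges) -> np.ndarray:
    """Minimum-image displacement vector(s) b - a for an orthorhombic box."""
    d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    edges = np.asarray(edges, dtype=float)
    return d - edges * np.round(d / edges)


def minimum_image_distance(a, b, box) -> float:
    """Shortest distance between two points over all periodic images.

    ``box`` is a :class:`~solvshell.ensemble.SimulationBox` (or anything with
    ``edge_lengths`` and ``periodic``); non-periodic boxes fall back to the
    direct distance.
    """
    if getattr(box, "periodic", True):
        d = minimum_image_displacement(a, b, box.edge_lengths)
    else:
        d = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    return float(np.linalg.norm(d, axis=-1)) if d.ndim == 1 else np.linalg.norm(d, axis=-1)
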