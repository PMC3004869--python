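"""Low-level vector geometry: torsions, bond angles, NeRF atom placement.

Angles cross the public interface in degrees; everything internal is radians.
"""
from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

# Below this sine of a bond/torsion angle the frame is numerically undefined.
_COLLINEAR_TOL = 1e-8


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> np.ndarray:
    """Signed torsion angle(s) in degrees in (-180, 180].

    Accepts single points of shape (3,) or stacks of shape (..., 3); the
    computation broadcasts over leading axes. IUPAC sign convention: looking
    from p1 to p2, clockwise rotation of p3 relative to p0 is positive.
    """
    b0 = np.asarray(p1) - np.asarray(p0)
    b1 = np.asarray(p2) - np.asarray(p1)
    b2 = np.asarray(p3) - np.asarray(p2)

    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    norm1 = np.linalg.norm(n1, axis=-1)
    norm2 = np.linalg.norm(n2, axis=-1)
    if np.any(norm1 < _COLLINEAR_TOL) or np.any(norm2 < _COLLINEAR_TOL):
        raise DegenerateGeometryError(
            "torsion undefined: three consecutive atoms are collinear"
        )
    b1u = b1 / np.linalg.norm(b1, axis=-1, keepdims=True)
    x = np.sum(n1 * n2, axis=-1)
    y = np.sum(np.cross(n1, n2) * b1u, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    # map -180 -> +180 so the range is (-180, 180]
    return np.where(np.isclose(ang, -180.0), 180.0, ang)


def bond_angle(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> np.ndarray:
    """Bond angle(s) p0-p1-p2 in degrees, broadcasting over leading axes."""
    v1 = np.asarray(p0) - np.asarray(p1)
    v2 = np.asarray(p2) - np.asarray(p1)
    v1 = v1 / np.linalg.norm(v1, axis=-1, keepdims=True)
    v2 = v2 / np.linalg.norm(v2, axis=-1, keepdims=True)
    cosang = np.clip(np.sum(v1 * v2, axis=-1), -1.0, 1.0)
    return np.degrees(np.arccos(cosang))


def place_atom(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond_length: float,
    angle_deg: float,
    torsion_deg: float,
) -> np.ndarray:
    """NeRF placement of atom d given the three preceding atoms a-b-c.

    d is placed at distance ``bond_length`` from c, with bond angle b-c-d
    equal to ``angle_deg`` and torsion a-b-c-d equal to ``torsion_deg``.
    """
    if not (0.0 < angle_deg < 180.0):
        raise DegenerateGeometryError(
            f"bond angle {angle_deg} deg gives a degenerate placement frame"
        )
    theta = np.radians(angle_deg)
    phi = np.radians(torsion_deg)

    bc = np.asarray(c, dtype=float) - np.asarray(b, dtype=float)
    bc_len = np.linalg.norm(bc)
    ab = np.asarray(b, dtype=float) - np.asarray(a, dtype=float)
    bc_hat = bc / bc_len
    n = np.cross(ab, bc)
    n_norm = np.linalg.norm(n)
    if bc_len < _COLLINEAR_TOL or n_norm < _COLLINEAR_TOL:
        raise DegenerateGeometryError("reference atoms are collinear")
    n_hat = n / n_norm
    m_hat = np.cross(n_hat, bc_hat)

    # local displacement in the (bc, m, n) frame
    d_local = bond_length * np.array(
        [
            -np.cos(theta),
            np.sin(theta) * np.cos(phi),
            np.sin(theta) * np.sin(phi),
        ]
    )
    return c + d_local[0] * bc_hat + d_local[1] * m_hat + d_local[2] * n_hat


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    """Dense n x n Euclidean distance matrix for an (n, 3) coordinate array."""
    diff = coords[:, None, :] - coords[None, :, :]
    return np.linalg.norm(diff, axis=-1)
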