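"""Shared 3D geometry primitives: superposition, rotations, internal
coordinates."""

from __future__ import annotations

import numpy as np

__all__ = [
    "kabsch", "rotation_about_axis", "rotation_angle_axis",
    "place_atom", "dihedral", "angle_between",
]


def kabsch(mobile: np.ndarray, reference: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` such that ``mobile @ R.T + t`` best fits
    ``reference``; the rotation is proper (det +1, no reflection).
    """
    mobile = np.asarray(mobile, dtype=np.float64)
    reference = np.asarray(reference, dtype=np.float64)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need >= 3 paired points of matching shape")
    cm, cr = mobile.mean(axis=0), reference.mean(axis=0)
    h = (mobile - cm).T @ (reference - cr)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = cr - rot @ cm
    moved = mobile @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((moved - reference) ** 2, axis=1))))
    return rot, trans, rmsd


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation matrix for a right-handed rotation about ``axis``."""
    u = np.asarray(axis, dtype=np.float64)
    u = u / np.linalg.norm(u)
    a = np.deg2rad(angle_deg)
    c, s = np.cos(a), np.sin(a)
    ux, uy, uz = u
    cross = np.array([[0, -uz, uy], [uz, 0, -ux], [-uy, ux, 0]])
    return c * np.eye(3) + s * cross + (1 - c) * np.outer(u, u)


def rotation_angle_axis(rot: np.ndarray,
                        degenerate_tol: float = 1e-8
                        ) -> tuple[float, np.ndarray]:
    """Decompose a rotation matrix into (angle in degrees, unit axis).

    The returned angle is positive in [0, 180]; the axis carries the sign
    (right-hand rule).  Raises ``ValueError`` when the rotation is within
    ``degenerate_tol`` of 0° or 180°, where the axis (or its sign) is not
    determined by the matrix.
    """
    rot = np.asarray(rot, dtype=np.float64)
    cos_a = np.clip((np.trace(rot) - 1.0) / 2.0, -1.0, 1.0)
    skew = np.array([rot[2, 1] - rot[1, 2],
                     rot[0, 2] - rot[2, 0],
                     rot[1, 0] - rot[0, 1]])
    sin_a = np.linalg.norm(skew) / 2.0
    angle = np.degrees(np.arctan2(sin_a, cos_a))
    if sin_a < degenerate_tol:
        if cos_a > 0:
            raise ValueError("rotation angle ~0; axis undefined")
        raise ValueError("rotation angle ~180; axis sign undefined")
    return float(angle), skew / (2.0 * sin_a)


def dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray,
             p3: np.ndarray) -> float:
    """Signed dihedral angle p0-p1-p2-p3 in degrees, in (-180, 180]."""
    b0, b1, b2 = p0 - p1, p2 - p1, p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Unsigned angle between two vectors in degrees."""
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond_length: float, bond_angle_deg: float,
               dihedral_deg: float) -> np.ndarray:
    """Place atom D from internal coordinates relative to atoms a-b-c.

    D sits at distance ``bond_length`` from c, with angle b-c-D equal to
    ``bond_angle_deg`` and dihedral a-b-c-D equal to ``dihedral_deg``
    (standard NeRF construction).
    """
    bc = c - b
    bc = bc / np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n = n / np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = np.deg2rad(bond_angle_deg)
    tor = np.deg2rad(dihedral_deg)
    return c + bond_length * (
        -np.cos(ang) * bc + np.sin(ang) * (np.cos(tor) * m + np.sin(tor) * n)
    )
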