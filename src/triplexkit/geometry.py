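"""Small rigid-body geometry toolbox shared by the frame and builder modules.

All rotations are proper (det = +1) 3x3 matrices acting on column vectors;
triads are stored as matrices whose *columns* are the x, y, z axes.
Angles are radians internally unless a function name says degrees.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "rotation_about_axis",
    "axis_angle_of",
    "kabsch",
    "signed_angle",
    "dihedral",
    "assert_rotation",
]


def rotation_about_axis(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rotation matrix about an arbitrary (not necessarily unit) axis."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [x * x * C + c, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, y * y * C + c, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, z * z * C + c],
        ]
    )


def axis_angle_of(R: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis and angle (in [0, pi]) of a proper rotation matrix.

    For the identity the axis is arbitrary; +z is returned with angle 0.
    """
    R = np.asarray(R, dtype=float)
    cos_t = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.arccos(cos_t))
    if angle < 1e-12:
        return np.array([0.0, 0.0, 1.0]), 0.0
    if np.pi - angle < 1e-7:
        # near 180 deg: axis from the symmetric part, R + I = 2 aa^T
        M = (R + np.eye(3)) / 2.0
        axis = np.sqrt(np.clip(np.diag(M), 0.0, None))
        # fix signs from off-diagonals using the largest component
        k = int(np.argmax(axis))
        if axis[k] > 0:
            for j in range(3):
                if j != k:
                    axis[j] = M[k, j] / axis[k]
        axis /= np.linalg.norm(axis)
        return axis, angle
    axis = np.array(
        [R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]]
    ) / (2.0 * np.sin(angle))
    return axis / np.linalg.norm(axis), angle


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of point set ``P`` onto ``Q``.

    Returns ``(R, t, rmsd)`` with ``Q ~= P @ R.T + t`` (row vectors), i.e.
    ``R`` maps P-frame coordinates into the Q frame.  Proper rotation is
    enforced (reflection branch corrected).
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("point sets must be matching (n, 3) arrays")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def signed_angle(v1: np.ndarray, v2: np.ndarray, ref: np.ndarray) -> float:
    """Signed angle from v1 to v2 about the reference axis (right-handed)."""
    v1 = np.asarray(v1, float)
    v2 = np.asarray(v2, float)
    ref = np.asarray(ref, float)
    return float(np.arctan2(np.dot(np.cross(v1, v2), ref / np.linalg.norm(ref)),
                            np.dot(v1, v2)))


def dihedral(p0, p1, p2, p3) -> float:
    """Dihedral angle of four points, IUPAC sign convention, in (-pi, pi]."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    b1, b2, b3 = p1 - p0, p2 - p1, p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-10 or np.linalg.norm(n2) < 1e-10:
        raise ValueError("dihedral undefined: three consecutive points are collinear")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = float(np.arctan2(np.dot(m, n2), np.dot(n1, n2)))
    return ang


def assert_rotation(R: np.ndarray, tol: float = 1e-8) -> None:
    """Raise if R is not orthonormal with determinant +1."""
    R = np.asarray(R, float)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R.T @ R, np.eye(3), atol=tol):
        raise ValueError("matrix is not orthonormal")
    if np.linalg.det(R) < 0:
        raise ValueError("matrix is a reflection, not a rotation")
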