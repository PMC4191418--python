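"""Shared independent oracles used across test modules."""

import numpy as np
from scipy.spatial.transform import Rotation


def quaternion_superpose(P, Q):
    """Horn's closed-form quaternion superposition: independent oracle.

    Returns (R, t) with Q ~= P @ R.T + t.
    """
    P = np.asarray(P, float)
    Q = np.asarray(Q, float)
    pc, qc = P.mean(0), Q.mean(0)
    A = P - pc
    B = Q - qc
    M = A.T @ B
    # 4x4 key matrix
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    N = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    w, v = np.linalg.eigh(N)
    q = v[:, -1]  # (w, x, y, z)
    R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    t = qc - R @ pc
    return R, t


def _mc_union_overlap(polysA, polysB, n_pts, rng):
    """Monte-Carlo area of intersection of two polygon unions (ray casting)."""

    def inside(poly, pts):
        x, y = pts[:, 0], pts[:, 1]
        n = len(poly)
        out = np.zeros(len(pts), dtype=bool)
        j = n - 1
        for i in range(n):
            xi, yi = poly[i]
            xj, yj = poly[j]
            cross = (yi > y) != (yj > y)
            xint = (xj - xi) * (y - yi) / (yj - yi) + xi
            out ^= cross & (x < xint)
            j = i
        return out

    allpts = np.vstack([p for p in polysA + polysB])
    lo, hi = allpts.min(0) - 0.1, allpts.max(0) + 0.1
    pts = rng.uniform(lo, hi, size=(n_pts, 2))
    inA = np.zeros(n_pts, bool)
    for p in polysA:
        inA |= inside(p, pts)
    inB = np.zeros(n_pts, bool)
    for p in polysB:
        inB |= inside(p, pts)
    box = np.prod(hi - lo)
    return box * (inA & inB).mean()
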