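"""Independent reference computations used to cross-check the package.

These deliberately take different algorithmic routes from the implementation:
quaternion (Horn) superposition instead of SVD Kabsch, scipy's Rotation for
axis-angle conversions, and brute-force scans instead of vectorised argmax.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation


def quaternion_superpose(mobile: np.ndarray, target: np.ndarray):
    """Horn's quaternion method for optimal rigid superposition.

    Returns (rotation 3x3, translation, rmsd).  Independent of the SVD
    route: builds the 4x4 key matrix from the cross-covariance and takes the
    eigenvector of its largest eigenvalue as the optimal quaternion.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    A = P - pc
    B = Q - qc
    M = A.T @ B
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(K)
    q = v[:, np.argmax(w)]  # (w, x, y, z)
    R = Rotation.from_quat([q[1], q[2], q[3], q[0]]).as_matrix()
    t = qc - R @ pc
    diff = P @ R.T + t - Q
    rmsd = float(np.sqrt((diff**2).sum() / len(P)))
    return R, t, rmsd


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def brute_force_peak(values: np.ndarray) -> tuple[int, int]:
    """Exhaustive argmax with smallest-row-then-column tie break."""
    best = None
    for i in range(values.shape[0]):
        for j in range(values.shape[1]):
            if best is None or values[i, j] > values[best]:
                best = (i, j)
    return best
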