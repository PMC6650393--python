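"""Helix-axis fitting and rigid-body superposition primitives.

These are the geometric building blocks of the lobe coordinate frame: each
helix is summarised by a straight axis fitted to its Cα trace, and the
pseudo-two-fold axis of a lobe is the rotation axis of the least-squares
superposition of one EF-hand onto the other.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HelixAxis",
    "Superposition",
    "fit_helix_axis",
    "kabsch_superpose",
    "axis_angle_of_rotation",
]


@dataclass(frozen=True)
class HelixAxis:
    """A straight-line fit to a helix Cα trace.

    ``direction`` is the unit principal axis of the centred coordinates,
    oriented from the N- toward the C-terminus; ``rms_residual`` is the
    root-mean-square perpendicular distance of the Cα from the fitted line.
    """

    direction: np.ndarray
    centroid: np.ndarray
    rms_residual: float
    n_residues: int


@dataclass(frozen=True)
class Superposition:
    """Optimal rigid map x -> rotation @ x + translation, with post-fit RMSD."""

    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, float) @ self.rotation.T + self.translation


def fit_helix_axis(ca_coords: np.ndarray) -> HelixAxis:
    """Fit a helix axis to an ordered Cα trace by an SVD line fit.

    The direction is the singular vector of the centred coordinates with the
    largest singular value, with sign chosen so it points from the first
    toward the last residue (N→C).  Requires at least 5 points.
    """
    X = np.asarray(ca_coords, dtype=float)
    if X.ndim != 2 or X.shape[1] != 3:
        raise ValueError("expected an (n, 3) coordinate array")
    n = len(X)
    if n < 5:
        raise ValueError(f"need at least 5 Cα to fit a helix axis, got {n}")
    centroid = X.mean(axis=0)
    C = X - centroid
    if not np.any(np.linalg.norm(C, axis=1) > 1e-9):
        raise ValueError("degenerate trace: all points coincident")
    _, s, vt = np.linalg.svd(C, full_matrices=False)
    direction = vt[0]
    span = X[-1] - X[0]
    if float(direction @ span) < 0:
        direction = -direction
    # perpendicular scatter about the line
    along = C @ direction
    perp2 = np.einsum("ij,ij->i", C, C) - along**2
    rms = float(np.sqrt(max(perp2.mean(), 0.0)))
    return HelixAxis(direction=direction, centroid=centroid,
                     rms_residual=rms, n_residues=n)


def kabsch_superpose(mobile: np.ndarray, target: np.ndarray) -> Superposition:
    """Least-squares rigid superposition of ``mobile`` onto ``target``.

    Classic SVD solution with the sign of the smallest singular vector
    corrected so the rotation is proper (det +1).  Returns the rotation,
    translation and post-fit RMSD over the paired points.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(target, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError(f"paired (n, 3) arrays required, got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise ValueError("need at least 3 point pairs")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (Q - qc).T @ (P - pc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0, 1.0, d])
    R = U @ D @ Vt
    t = qc - R @ pc
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.einsum("ij,ij->", diff, diff) / len(P)))
    return Superposition(rotation=R, translation=t, rmsd=rmsd)


def axis_angle_of_rotation(rotation: np.ndarray) -> tuple[np.ndarray, float]:
    """Axis–angle decomposition of a proper rotation matrix.

    Returns ``(axis, angle_degrees)`` with the angle in [0, 180].  The
    identity is reported as angle 0 about (0, 0, 1) by convention.  At
    180° the axis sign is inherently ambiguous; callers that need a fixed
    sign (the lobe-frame construction) apply their own convention.
    """
    R = np.asarray(rotation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-6) \
            or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper orthonormal rotation matrix")
    cos_t = np.clip((np.trace(R) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_t)))
    if angle < 1e-9:
        return np.array([0.0, 0.0, 1.0]), 0.0
    # eigenvector of R for eigenvalue +1, robust near 180° where the
    # antisymmetric part vanishes
    w, v = np.linalg.eigh((R + R.T) / 2.0)
    axis = v[:, np.argmax(w)]
    skew = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    if np.linalg.norm(skew) > 1e-9:
        axis = skew / np.linalg.norm(skew)
    else:
        axis = axis / np.linalg.norm(axis)
    return axis, angle
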