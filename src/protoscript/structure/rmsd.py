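"""Kabsch superposition and CA RMSD."""

from __future__ import annotations

import numpy as np

from ..errors import StructureError
from .pose import Pose

__all__ = ["kabsch", "superpose_rmsd", "rmsd_no_superposition"]


def kabsch(P: np.ndarray, Q: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal proper rotation R and translation t minimising |R P + t - Q|.

    Returns (R, t, rmsd).  Degenerate (collinear or coincident) point sets
    are reported as an error since their rotation is not unique.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise StructureError(f"point sets must have equal (n,3) shapes, got {P.shape} vs {Q.shape}")
    if len(P) < 3:
        raise StructureError("superposition needs at least 3 points")
    cp = P.mean(axis=0)
    cq = Q.mean(axis=0)
    H = (P - cp).T @ (Q - cq)
    U, S, Vt = np.linalg.svd(H)
    if S[1] <= 1e-8 * max(S[0], 1e-300):
        raise StructureError("degenerate (collinear) point set: rotation is not unique")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))
    return R, t, rmsd


def rmsd_no_superposition(P: np.ndarray, Q: np.ndarray) -> float:
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise StructureError("point sets must have equal shapes")
    diff = P - Q
    return float(np.sqrt(np.mean(np.sum(diff * diff, axis=1))))


def superpose_rmsd(
    pose_a: Pose,
    pose_b: Pose,
    subset: list[int] | None = None,
    superimpose: bool = True,
) -> float:
    """CA RMSD between two poses over a residue subset (pose numbering).

    With ``superimpose`` the optimal least-squares rigid superposition
    (Kabsch, proper rotation enforced) is applied first.
    """
    if subset is None:
        subset_a = [i for i, r in pose_a.residues() if r.is_protein]
        subset_b = [i for i, r in pose_b.residues() if r.is_protein]
    else:
        subset_a = subset_b = list(subset)
    A = pose_a.ca_coords(subset_a)
    B = pose_b.ca_coords(subset_b)
    if A.shape != B.shape:
        raise StructureError(
            f"subset size mismatch: {A.shape[0]} vs {B.shape[0]} CA atoms"
        )
    if not superimpose:
        return rmsd_no_superposition(A, B)
    if len(A) < 3:
        raise StructureError("superposition needs at least 3 residues")
    _, _, value = kabsch(A, B)
    return value
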