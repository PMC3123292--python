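"""Rigid-body minimisation with numerical gradients.

The movable degrees of freedom are the 6 rigid-body parameters (rotation
vector about the chain centroid + translation) of every chain the MoveMap
marks rigid-body-movable.  The objective is the score-function total plus,
when Calpha restraints are enabled (sigma > 0), a harmonic penalty
k * |dCA|^2 per backbone-movable residue with k = 1 / (2 sigma^2), taken
from each CA's position at minimiser entry.

Steepest descent with central-difference gradients and backtracking line
search: the energy never increases across accepted steps.  Terminates when
the best achievable improvement drops below ``tol`` or after ``max_iter``
iterations.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

from ..errors import ProtocolError
from ..structure.pose import Pose
from ..structure.scorefxn import ScoreFunction, score
from .movemap import MoveMap

__all__ = ["minimize_pose"]


def _apply_dofs(base: Pose, chains: list[str], centers: list[np.ndarray], x: np.ndarray) -> Pose:
    work = base.copy()
    for k, chain in enumerate(chains):
        t = x[6 * k : 6 * k + 3]
        rv = x[6 * k + 3 : 6 * k + 6]
        R = Rotation.from_rotvec(rv).as_matrix()
        work.rotate_chain_about(chain, R, centers[k])
        work.translate_chain(chain, t)
    return work


def minimize_pose(
    pose: Pose,
    sfx: ScoreFunction,
    movemap: MoveMap,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> float:
    """Minimise in place; returns the final objective value."""
    chains = sorted(movemap.rb_chains)
    if not chains:
        raise ProtocolError("movemap enables no rigid-body degrees of freedom")
    centers = [pose.chain_centroid(c) for c in chains]
    sigma = movemap.calpha_restraints
    k_restraint = 1.0 / (2.0 * sigma * sigma) if sigma > 0 else 0.0
    restrained = sorted(movemap.bb) if k_restraint > 0 else []
    ca_ref = (
        np.asarray([pose.residue(i).atoms["CA"] for i in restrained])
        if restrained
        else None
    )

    def objective(x: np.ndarray) -> float:
        work = _apply_dofs(pose, chains, centers, x)
        e = score(work, sfx).total
        if ca_ref is not None:
            ca_now = np.asarray([work.residue(i).atoms["CA"] for i in restrained])
            e += k_restraint * float(np.sum((ca_now - ca_ref) ** 2))
        return e

    n = 6 * len(chains)
    x = np.zeros(n)
    energy = objective(x)
    h = 1e-4
    step0 = 0.5
    for _ in range(max_iter):
        grad = np.empty(n)
        for d in range(n):
            e = np.zeros(n)
            e[d] = h
            grad[d] = (objective(x + e) - objective(x - e)) / (2 * h)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < 1e-12:
            break
        direction = -grad / gnorm
        alpha = step0
        improved = False
        for _ in range(30):
            trial = x + alpha * direction
            e_trial = objective(trial)
            if e_trial < energy - 1e-15:
                improvement = energy - e_trial
                x, energy = trial, e_trial
                improved = True
                break
            alpha *= 0.5
        if not improved or improvement < tol:
            break
    final = _apply_dofs(pose, chains, centers, x)
    pose.assign(final)
    return energy
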