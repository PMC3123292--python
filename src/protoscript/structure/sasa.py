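"""Solvent-accessible surface area by sphere-point sampling (Shrake-Rupley).

Sample points are placed on each expanded sphere (site radius + probe) with
a deterministic golden-spiral construction, so results are exactly
reproducible without any random source.  A point is buried when it falls
inside any other site's expanded sphere; the accessible area of a site is
the free fraction of its expanded-sphere area, and residue/total SASA are
sums over sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import StructureError
from .pose import Pose

__all__ = ["compute_sasa", "sasa_fractions", "golden_spiral", "SasaResult"]

DEFAULT_PROBE = 1.4  # Angstrom, water-sized probe
DEFAULT_N_POINTS = 960


def golden_spiral(n: int) -> np.ndarray:
    """n near-uniform points on the unit sphere (deterministic)."""
    k = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


@dataclass
class SasaResult:
    per_residue: dict[int, float]  # pose index -> area (A^2)
    total: float


def _site_table(pose: Pose):
    pos, rad, chg, ridx, cidx = pose.site_arrays()
    return pos, rad, ridx


def _sasa_of_sites(
    pos: np.ndarray, rad: np.ndarray, probe: float, points: np.ndarray
) -> np.ndarray:
    """Accessible area per site."""
    n = len(pos)
    expanded = rad + probe
    areas = np.empty(n)
    for i in range(n):
        ri = expanded[i]
        d = np.linalg.norm(pos - pos[i], axis=1)
        nbr = np.flatnonzero((d < ri + expanded) & (np.arange(n) != i))
        full = 4.0 * np.pi * ri * ri
        if nbr.size == 0:
            areas[i] = full
            continue
        surf = pos[i] + ri * points  # (k,3)
        diff = surf[:, None, :] - pos[nbr][None, :, :]
        buried = np.any(
            np.einsum("kjd,kjd->kj", diff, diff) < (expanded[nbr] ** 2)[None, :],
            axis=1,
        )
        areas[i] = full * float(np.count_nonzero(~buried)) / len(points)
    return areas


def compute_sasa(
    pose: Pose, probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS
) -> SasaResult:
    """Per-residue and total SASA of a pose (A^2)."""
    if n_points < 32:
        raise StructureError(f"n_points must be >= 32, got {n_points}")
    if len(pose) == 0:
        raise StructureError("cannot compute SASA of an empty pose")
    pos, rad, ridx = _site_table(pose)
    points = golden_spiral(n_points)
    areas = _sasa_of_sites(pos, rad, probe, points)
    per_residue: dict[int, float] = {i: 0.0 for i, _ in pose.residues()}
    for area, i in zip(areas, ridx):
        per_residue[int(i)] += float(area)
    return SasaResult(per_residue=per_residue, total=float(np.sum(areas)))


def sasa_fractions(
    pose: Pose, probe: float = DEFAULT_PROBE, n_points: int = DEFAULT_N_POINTS
) -> dict[int, float]:
    """Per-residue SASA divided by the same residue's SASA computed in
    isolation (occluded only by its own sites); used for burial layers."""
    if n_points < 32:
        raise StructureError(f"n_points must be >= 32, got {n_points}")
    in_context = compute_sasa(pose, probe, n_points).per_residue
    points = golden_spiral(n_points)
    fractions: dict[int, float] = {}
    for i, res in pose.residues():
        sites = list(res.sites())
        pos = np.asarray([s[1] for s in sites], dtype=float)
        rad = np.asarray([s[2] for s in sites], dtype=float)
        isolated = float(np.sum(_sasa_of_sites(pos, rad, probe, points)))
        fractions[i] = in_context[i] / isolated if isolated > 0 else 0.0
    return fractions
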