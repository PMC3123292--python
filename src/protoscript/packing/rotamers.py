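"""Discrete side-chain candidates (rotamers) for the reduced model.

Each packable residue gets, for every allowed amino-acid type, k centroid
placements on a deterministic sphere grid around its CA at the type's
CA-centroid distance (k = 3, or 6 with extra rotamer density).  When the
task requests it, the current conformation is appended as an extra
candidate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..structure import chem
from ..structure.pose import Pose
from ..structure.sasa import golden_spiral
from .task import PackerTask

__all__ = ["Rotamer", "RotamerSet", "build_rotamers"]


@dataclass(frozen=True)
class Rotamer:
    aa: str  # one-letter code
    centroid: tuple[float, float, float]

    @property
    def position(self) -> np.ndarray:
        return np.asarray(self.centroid)


@dataclass
class RotamerSet:
    """Candidates per packable residue (pose index -> ordered rotamers)."""

    candidates: dict[int, list[Rotamer]]

    def sites(self) -> list[int]:
        return list(self.candidates)

    def __getitem__(self, i: int) -> list[Rotamer]:
        return self.candidates[i]

    def n_assignments(self) -> int:
        n = 1
        for rots in self.candidates.values():
            n *= len(rots)
        return n


def build_rotamers(
    pose: Pose,
    task: PackerTask,
    include_current: bool | None = None,
    extra_density: bool | None = None,
) -> RotamerSet:
    """Build candidates for every packable residue of a finalized task."""
    if include_current is None:
        include_current = task.include_current
    if extra_density is None:
        extra_density = task.extra_density
    k = 6 if extra_density else 3
    directions = golden_spiral(k)
    candidates: dict[int, list[Rotamer]] = {}
    for i in task.packable_indices():
        res = pose.residue(i)
        spec = task.spec(i)
        ca = res.atoms["CA"]
        rots: list[Rotamer] = []
        for letter in sorted(spec.allowed):
            aa = chem.AMINO_ACIDS[letter]
            for d in directions:
                pos = ca + aa.ca_centroid_distance * d
                rots.append(Rotamer(letter, tuple(map(float, pos))))
        if include_current and res.centroid is not None and res.letter:
            rots.append(Rotamer(res.letter, tuple(map(float, res.centroid))))
        if rots:
            candidates[i] = rots
    return RotamerSet(candidates)
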