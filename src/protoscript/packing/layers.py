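"""Burial-layer assignment and per-layer design alphabets.

A residue's burial is the ratio of its SASA in the pose to its SASA in
isolation.  Ratios below 0.10 are ``core``, above 0.40 ``surface``, and
``boundary`` otherwise.  Layer-restricted design allows hydrophobic types
in the core, polar types on the surface, and their union at the boundary.
"""

from __future__ import annotations

from ..structure.pose import Pose
from ..structure.sasa import sasa_fractions

__all__ = ["layer_assign", "LAYER_ALPHABETS", "CORE_MAX", "SURFACE_MIN"]

CORE_MAX = 0.10
SURFACE_MIN = 0.40

_CORE = set("AVILMFWY")
_SURFACE = set("DEGHKNPQRST")

LAYER_ALPHABETS = {
    "core": frozenset(_CORE),
    "surface": frozenset(_SURFACE),
    "boundary": frozenset(_CORE | _SURFACE),
}


def layer_assign(pose: Pose) -> dict[int, str]:
    """Per-residue layer for the protein residues of a pose."""
    fractions = sasa_fractions(pose)
    layers: dict[int, str] = {}
    for i, res in pose.residues():
        if not res.is_protein:
            continue
        frac = fractions[i]
        if frac < CORE_MAX:
            layers[i] = "core"
        elif frac > SURFACE_MIN:
            layers[i] = "surface"
        else:
            layers[i] = "boundary"
    return layers
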