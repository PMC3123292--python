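"""MoveMap: which degrees of freedom a minimisation may touch.

In the reduced representation the sampled degrees of freedom are per-chain
rigid-body transforms; backbone/side-chain flags are recorded per residue
and feed interface restriction and the Calpha-restraint term (there are no
backbone torsion DOFs to move).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["MoveMap"]


@dataclass
class MoveMap:
    bb: set[int] = field(default_factory=set)  # backbone-movable residues
    sc: set[int] = field(default_factory=set)  # side-chain-movable residues
    rb_chains: set[str] = field(default_factory=set)  # rigid-body-movable chains
    calpha_restraints: float = 0.0  # sigma (A); 0 disables the restraint

    def n_dof(self) -> int:
        return 6 * len(self.rb_chains)
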