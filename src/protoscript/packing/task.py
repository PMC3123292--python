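"""PackerTask: per-residue design/repack state under restriction-only ops.

A fresh task starts maximally permissive -- every protein residue packable
and designable with all twenty amino acids allowed -- and task operations
may only *restrict* it: clear the packable/designable flags or intersect
the allowed amino-acid set.  Nothing is ever re-enabled, which is what makes
the operation algebra commutative: the final task is a pure intersection of
the restrictions, independent of application order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import StructureError, TaskError
from ..structure import chem
from ..structure.pose import Pose

__all__ = ["ResidueSpec", "PackerTask", "default_task", "apply_taskops"]


@dataclass
class ResidueSpec:
    packable: bool
    designable: bool
    allowed: set[str]
    behaviors: set[str] = field(default_factory=set)
    native: str | None = None

    def __eq__(self, other):
        if not isinstance(other, ResidueSpec):
            return NotImplemented
        return (
            self.packable == other.packable
            and self.designable == other.designable
            and self.allowed == other.allowed
            and self.behaviors == other.behaviors
            and self.native == other.native
        )


class PackerTask:
    """One-time-use search-space specification for the packer."""

    def __init__(self, pose: Pose):
        if len(pose) == 0:
            raise StructureError("cannot build a PackerTask for an empty pose")
        self.pose = pose
        self.include_current = False
        self.extra_density = False
        self._specs: dict[int, ResidueSpec] = {}
        for i, res in pose.residues():
            if res.is_protein:
                self._specs[i] = ResidueSpec(
                    packable=True,
                    designable=True,
                    allowed=set(chem.ALL_LETTERS),
                    native=res.letter,
                )
            else:
                # ligand / nucleic residues never pack in this engine
                self._specs[i] = ResidueSpec(
                    packable=False, designable=False, allowed=set(), native=None
                )

    # -- access ----------------------------------------------------------

    def spec(self, i: int) -> ResidueSpec:
        if i not in self._specs:
            raise TaskError(f"no residue {i} in task (1..{len(self._specs)})")
        return self._specs[i]

    def residue_indices(self) -> list[int]:
        return list(self._specs)

    def packable_indices(self) -> list[int]:
        return [i for i, s in self._specs.items() if s.packable]

    def designable_indices(self) -> list[int]:
        return [i for i, s in self._specs.items() if s.designable]

    # -- restriction-only operations --------------------------------------
    # every mutator below only shrinks allowed sets / clears flags

    def restrict_to_repacking(self, i: int) -> None:
        s = self.spec(i)
        s.designable = False
        if s.native is not None:
            s.allowed &= {s.native}

    def prevent_repacking(self, i: int) -> None:
        s = self.spec(i)
        s.packable = False
        s.designable = False
        if s.native is not None:
            s.allowed &= {s.native}

    def restrict_allowed(self, i: int, aas: set[str]) -> None:
        s = self.spec(i)
        s.allowed &= set(aas)

    def add_behavior(self, i: int, behavior: str) -> None:
        self.spec(i).behaviors.add(behavior)

    def set_include_current(self) -> None:
        self.include_current = True

    def set_extra_density(self) -> None:
        self.extra_density = True

    # -- finalization ------------------------------------------------------

    def finalize(self) -> "PackerTask":
        """Normalise invariants in place and return self: a residue whose
        allowed set became empty reverts to native repack-only; a
        non-packable residue allows only its native type."""
        for s in self._specs.values():
            if not s.packable:
                s.designable = False
                s.allowed = {s.native} if s.native is not None else set()
            elif not s.allowed:
                s.allowed = {s.native} if s.native is not None else set()
                s.designable = False
            elif s.allowed == {s.native}:
                s.designable = False
        return self

    # -- identity / debugging ---------------------------------------------

    def __eq__(self, other):
        if not isinstance(other, PackerTask):
            return NotImplemented
        return (
            self._specs == other._specs
            and self.include_current == other.include_current
            and self.extra_density == other.extra_density
        )

    def to_tsv(self) -> str:
        """Tab-separated dump: residue, chain, packable, designable, allowed."""
        lines = ["residue\tchain\tpackable\tdesignable\tallowed"]
        for i, s in self._specs.items():
            res = self.pose.residue(i)
            lines.append(
                "\t".join(
                    [
                        str(res.pdb_number),
                        res.chain_id,
                        "1" if s.packable else "0",
                        "1" if s.designable else "0",
                        "".join(sorted(s.allowed)),
                    ]
                )
            )
        return "\n".join(lines) + "\n"


def default_task(pose: Pose) -> PackerTask:
    """The maximally permissive task: redesign all protein residues allowing
    all amino acids; non-protein residues are not packable."""
    return PackerTask(pose)


def apply_taskops(task: PackerTask, ops) -> PackerTask:
    """Apply task operations in sequence.  The result is independent of the
    order because every operation only intersects/clears."""
    for op in ops:
        op.apply(task)
    return task
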