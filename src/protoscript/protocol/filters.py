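"""Built-in filters: binding energy (ddG), buried SASA, RMSD, logical
composition, and constant filters.

All filters evaluate a pose without modifying it and report a numeric
value alongside the pass/fail verdict.
"""

from __future__ import annotations

import numpy as np

from ..errors import ProtocolError, StructureError
from ..packing.annealer import pack_anneal
from ..packing.task import default_task
from ..structure.pose import Pose
from ..structure.rmsd import superpose_rmsd
from ..structure.sasa import compute_sasa
from ..structure.scorefxn import ScoreFunction, score
from .base import Filter

__all__ = [
    "DdgFilter",
    "SasaFilter",
    "RmsdFilter",
    "CompoundStatement",
    "FalseFilter",
    "TrueFilter",
    "partition_chains",
    "separated_pose",
]

SEPARATION_VECTOR = np.array([500.0, 0.0, 0.0])  # beyond every cutoff
INTERFACE_REPACK_CUTOFF = 12.0  # A, centroid cross-chain distance


def partition_chains(pose: Pose) -> tuple[list[str], list[str]]:
    """Two-body partition: first chain vs the rest."""
    chains = pose.chains()
    if len(chains) < 2:
        raise StructureError(
            f"a two-body pose is required, got chains {chains}"
        )
    return [chains[0]], chains[1:]


def separated_pose(pose: Pose) -> Pose:
    """Copy with the second partner translated +500 A along x."""
    _, partner_b = partition_chains(pose)
    out = pose.copy()
    for chain in partner_b:
        out.translate_chain(chain, SEPARATION_VECTOR)
    return out


def interface_residues(pose: Pose, cutoff: float = INTERFACE_REPACK_CUTOFF) -> set[int]:
    """Protein residues whose reference point (centroid, or first atom for
    ligands) lies within ``cutoff`` of any residue of another chain."""

    def refpoint(res):
        if res.centroid is not None:
            return res.centroid
        return next(iter(res.atoms.values()))

    points = {i: refpoint(r) for i, r in pose.residues()}
    out: set[int] = set()
    for i, res in pose.residues():
        if not res.is_protein:
            continue
        for j, other in pose.residues():
            if other.chain_id == res.chain_id:
                continue
            if np.linalg.norm(points[i] - points[j]) < cutoff:
                out.add(i)
                break
    return out


class DdgFilter(Filter):
    """Computed binding energy: score of the bound complex minus the
    separated partners, the separated state re-packed at the interface.
    Averaged over ``repeats`` runs (repack seed = repeat index) for better
    numerical stability.  Passes when ddG <= threshold."""

    key_name = "Ddg"

    def __init__(self, sfx: ScoreFunction | None = None, threshold: float = 0.0, repeats: int = 1):
        super().__init__()
        self.sfx = sfx
        self.threshold = threshold
        self.repeats = repeats

    def parse_my_tag(self, tag, data, filters, movers):
        self.parse_confidence(tag)
        self.sfx = data.get(
            "scorefxns", tag.get_option("scorefxn", str, "score12"), ScoreFunction
        )
        self.threshold = tag.get_option("threshold", float, 0.0)
        self.repeats = tag.get_option("repeats", int, 1)
        if self.repeats < 1:
            raise ProtocolError(f"Ddg repeats must be >= 1, got {self.repeats}")

    def report_value(self, pose):
        if self.repeats < 1:
            raise ProtocolError("Ddg repeats must be >= 1")
        bound = score(pose, self.sfx).total
        iface = interface_residues(pose)
        values = []
        for repeat in range(1, self.repeats + 1):
            apart = separated_pose(pose)
            task = default_task(apart)
            for i in task.residue_indices():
                task.restrict_to_repacking(i)
                if i not in iface:
                    task.prevent_repacking(i)
            if task.packable_indices():
                apart, unbound = pack_anneal(apart, self.sfx, task, seed=repeat)
            else:
                unbound = score(apart, self.sfx).total
            values.append(bound - unbound)
        return float(np.mean(values))

    def apply(self, pose):
        return self.report_value(pose) <= self.threshold


class SasaFilter(Filter):
    """Buried surface area on complex formation:
    SASA(A) + SASA(B) - SASA(AB).  Passes when >= threshold."""

    key_name = "Sasa"

    def __init__(self, threshold: float = 800.0):
        super().__init__()
        self.threshold = threshold

    def parse_my_tag(self, tag, data, filters, movers):
        self.parse_confidence(tag)
        self.threshold = tag.get_option("threshold", float, 800.0)

    def report_value(self, pose):
        a, b = partition_chains(pose)
        sasa_ab = compute_sasa(pose).total
        sasa_a = compute_sasa(pose.subpose(a)).total
        sasa_b = compute_sasa(pose.subpose(b)).total
        return sasa_a + sasa_b - sasa_ab

    def apply(self, pose):
        return self.report_value(pose) >= self.threshold


class RmsdFilter(Filter):
    """CA RMSD from the starting structure (superimposed).
    Passes when <= threshold (default: always)."""

    key_name = "Rmsd"

    def __init__(self, threshold: float = float("inf"), superimpose: bool = True):
        super().__init__()
        self.threshold = threshold
        self.superimpose = superimpose

    def parse_my_tag(self, tag, data, filters, movers):
        self.parse_confidence(tag)
        self.threshold = tag.get_option("threshold", float, float("inf"))
        self.superimpose = tag.get_option("superimpose", bool, True)

    def report_value(self, pose):
        if pose.start_coords is None:
            raise ProtocolError("pose has no starting-coordinates snapshot")
        subset = [i for i, r in pose.residues() if r.is_protein]
        now = pose.ca_coords(subset)
        ref = np.asarray([pose.start_coords[i]["CA"] for i in subset])
        from ..structure.rmsd import kabsch, rmsd_no_superposition

        if not self.superimpose:
            return rmsd_no_superposition(now, ref)
        _, _, value = kabsch(now, ref)
        return value

    def apply(self, pose):
        return self.report_value(pose) <= self.threshold


class CompoundStatement(Filter):
    """Fold sub-filters left-to-right with AND/OR/XOR connectives; each
    clause may be negated.  The first clause's connective is ignored."""

    key_name = "CompoundStatement"

    def __init__(self, clauses=None):
        super().__init__()
        #: list of (connective, filter, negate)
        self.clauses: list[tuple[str, Filter, bool]] = list(clauses or [])

    def parse_my_tag(self, tag, data, filters, movers):
        self.parse_confidence(tag)
        self.clauses = []
        for sub in tag.subtags:
            if sub.name not in ("AND", "OR", "XOR"):
                raise ProtocolError(
                    f"CompoundStatement clause <{sub.name}> must be AND, OR or XOR"
                )
            fname = sub.get_option("filter_name", str, None) or sub.get_option("filter")
            if fname not in filters:
                raise ProtocolError(
                    f"CompoundStatement refers to undeclared filter {fname!r}"
                )
            negate = sub.get_option("negate", bool, False)
            self.clauses.append((sub.name, filters[fname], negate))
        if not self.clauses:
            raise ProtocolError("CompoundStatement with zero subfilters")

    def apply(self, pose):
        if not self.clauses:
            raise ProtocolError("CompoundStatement with zero subfilters")
        result: bool | None = None
        for connective, filt, negate in self.clauses:
            value = bool(filt.apply(pose))
            if negate:
                value = not value
            if result is None:
                result = value
            elif connective == "AND":
                result = result and value
            elif connective == "OR":
                result = result or value
            else:
                result = result != value
        return bool(result)

    def report_value(self, pose):
        return float(self.apply(pose))


class FalseFilter(Filter):
    """Always fails (used to exhaust LoopOver iterations)."""

    key_name = "FalseFilter"

    def parse_my_tag(self, tag, data, filters, movers):
        self.parse_confidence(tag)

    def apply(self, pose):
        return False

    def report_value(self, pose):
        return 0.0


class TrueFilter(Filter):
    """Always passes."""

    key_name = "TrueFilter"

    def parse_my_tag(self, tag, data, filters, movers):
        self.parse_confidence(tag)

    def apply(self, pose):
        return True

    def report_value(self, pose):
        return 1.0
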