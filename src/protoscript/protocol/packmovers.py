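"""Packing movers: PackRotamersMover and RepackMinimize."""

from __future__ import annotations

import numpy as np

from ..errors import DataMapKeyError, ProtocolError, StructureError
from ..packing.annealer import pack_anneal
from ..packing.task import apply_taskops, default_task
from ..packing.taskops import TaskOperation
from ..structure.scorefxn import ScoreFunction
from .base import Mover, Status, pose_rng
from .minimize import minimize_pose
from .movemap import MoveMap

__all__ = ["PackRotamersMover", "RepackMinimize"]

INTERFACE_DESIGN_CUTOFF = 8.0  # A: cross-chain centroid distance -> designable
INTERFACE_REPACK_CUTOFF = 12.0  # A: -> repackable


class PackRotamersMover(Mover):
    """Invoke the packer to design or repack side chains under the task
    operations listed in ``task_operations`` (resolved through the DataMap)."""

    key_name = "PackRotamersMover"

    def __init__(self, sfx: ScoreFunction | None = None, task_operations=()):
        super().__init__()
        self.sfx = sfx
        self.task_operations: list[TaskOperation] = list(task_operations)

    def parse_my_tag(self, tag, data, filters, movers):
        self.sfx = data.get(
            "scorefxns", tag.get_option("scorefxn", str, "score12"), ScoreFunction
        )
        self.task_operations = []
        for opname in tag.get_option_list("task_operations", str, []):
            try:
                op = data.get("task_operations", opname, TaskOperation)
            except DataMapKeyError as exc:
                raise ProtocolError(
                    f"{self.key_name} {tag.get_option('name', str, '?')!r}: "
                    f"task operation {opname!r} not found: {exc}"
                ) from exc
            self.task_operations.append(op)

    def apply(self, pose) -> Status:
        task = default_task(pose)
        apply_taskops(task, self.task_operations)
        seed = int(pose_rng(pose).integers(2**31))
        packed, energy = pack_anneal(pose, self.sfx, task, seed=seed)
        pose.assign(packed)
        self.extras = {"packed_energy": energy}
        return Status.SUCCESS


def interface_task(pose, design_partner1: bool, design_partner2: bool):
    """Interface task for a two-body pose: residues whose centroid lies
    within 8 A of the other partner are designable, within 12 A repackable,
    and frozen otherwise; the design flags can disable design per partner."""
    chains = pose.chains()
    if len(chains) < 2:
        raise StructureError("RepackMinimize needs at least two chains")
    partner1 = {chains[0]}
    task = default_task(pose)

    def refpoint(res):
        return res.centroid if res.centroid is not None else next(iter(res.atoms.values()))

    for i, res in pose.residues():
        if not res.is_protein:
            continue
        dmin = min(
            (
                float(np.linalg.norm(refpoint(res) - refpoint(other)))
                for _, other in pose.residues()
                if other.chain_id != res.chain_id
            ),
            default=float("inf"),
        )
        in_p1 = res.chain_id in partner1
        design_ok = design_partner1 if in_p1 else design_partner2
        if dmin < INTERFACE_DESIGN_CUTOFF and design_ok:
            pass  # stays designable
        elif dmin < INTERFACE_REPACK_CUTOFF:
            task.restrict_to_repacking(i)
        else:
            task.prevent_repacking(i)
    return task


class RepackMinimize(Mover):
    """Interface repack/design with one score function followed by
    rigid-body minimisation with another.

    ``minimize_rb`` frees the second partner's rigid-body transform;
    ``minimize_bb`` records backbone freedom in the MoveMap (no backbone
    torsion DOFs exist in the reduced model, so coordinates of each chain's
    backbone change only through rigid-body motion)."""

    key_name = "RepackMinimize"

    def __init__(
        self,
        sfx_repack: ScoreFunction | None = None,
        sfx_minimize: ScoreFunction | None = None,
        minimize_bb: bool = False,
        minimize_rb: bool = True,
        design_partner1: bool = True,
        design_partner2: bool = True,
    ):
        super().__init__()
        self.sfx_repack = sfx_repack
        self.sfx_minimize = sfx_minimize
        self.minimize_bb = minimize_bb
        self.minimize_rb = minimize_rb
        self.design_partner1 = design_partner1
        self.design_partner2 = design_partner2

    def parse_my_tag(self, tag, data, filters, movers):
        self.sfx_repack = data.get(
            "scorefxns", tag.get_option("scorefxn_repack", str, "score12"), ScoreFunction
        )
        self.sfx_minimize = data.get(
            "scorefxns", tag.get_option("scorefxn_minimize", str, "score12"), ScoreFunction
        )
        self.minimize_bb = tag.get_option("minimize_bb", bool, False)
        self.minimize_rb = tag.get_option("minimize_rb", bool, True)
        design = tag.get_option("design", bool, True)
        self.design_partner1 = tag.get_option("design_partner1", bool, design)
        self.design_partner2 = tag.get_option("design_partner2", bool, design)

    def apply(self, pose) -> Status:
        task = interface_task(pose, self.design_partner1, self.design_partner2)
        if task.packable_indices():
            seed = int(pose_rng(pose).integers(2**31))
            packed, _ = pack_anneal(pose, self.sfx_repack, task, seed=seed)
            pose.assign(packed)
        if self.minimize_rb:
            chains = pose.chains()
            movemap = MoveMap(rb_chains=set(chains[1:]))
            if self.minimize_bb:
                movemap.bb = {i for i, r in pose.residues() if r.is_protein}
            minimize_pose(pose, self.sfx_minimize, movemap)
        return Status.SUCCESS
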