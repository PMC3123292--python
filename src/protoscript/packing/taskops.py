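"""Built-in task operations.

Three kinds exist: uniform (no options, e.g. RestrictToRepacking),
parameterised (e.g. ReadResfile), and residue-level operations applied to a
selected subset (OperateOnCertainResidues with one residue selector and one
residue-level operation).  All of them are restriction-only, so any set of
operations commutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..datamap import DataMap
from ..errors import TaskError, ValidationError
from ..registry import (
    Creator,
    Factory,
    placeholder_creator,
    task_operation_factory,
)
from ..structure.pose import Pose
from ..tagparse import Tag
from .layers import LAYER_ALPHABETS, layer_assign
from .resfile import load_resfile
from .task import PackerTask

__all__ = [
    "TaskOperation",
    "PackerGlobals",
    "parse_task_operation",
    "parse_taskoperations_block",
    "read_resfile",
]


@dataclass
class PackerGlobals:
    """Run-configuration packer options (the command-line surface)."""

    extra_density: bool = False
    include_current: bool = False


class TaskOperation:
    """Restriction procedure on a PackerTask; never enlarges the search."""

    key_name: str = ""

    def __init__(self):
        self.name: str | None = None

    def parse_my_tag(self, tag: Tag, data: DataMap | None) -> None:
        pass

    def apply(self, task: PackerTask) -> None:
        raise NotImplementedError


class InitializeFromCommandline(TaskOperation):
    """Forward run-configuration packer globals into the task."""

    key_name = "InitializeFromCommandline"

    def __init__(self):
        super().__init__()
        self.globals = PackerGlobals()

    def parse_my_tag(self, tag, data):
        if data is not None and data.has("config", "packer_globals"):
            self.globals = data.get("config", "packer_globals", PackerGlobals)

    def apply(self, task):
        if self.globals.extra_density:
            task.set_extra_density()
        if self.globals.include_current:
            task.set_include_current()


class IncludeCurrent(TaskOperation):
    """Add each residue's current conformation to its rotamer candidates."""

    key_name = "IncludeCurrent"

    def apply(self, task):
        task.set_include_current()


class RestrictToRepacking(TaskOperation):
    """Only repack; do not design (all residues)."""

    key_name = "RestrictToRepacking"

    def apply(self, task):
        for i in task.residue_indices():
            task.restrict_to_repacking(i)


class ReadResfile(TaskOperation):
    """Apply an external resfile's per-residue packing commands."""

    key_name = "ReadResfile"

    def __init__(self, filename: str | None = None):
        super().__init__()
        self.filename = filename

    def parse_my_tag(self, tag, data):
        self.filename = tag.get_option("filename")

    def apply(self, task):
        if not self.filename:
            raise TaskError("ReadResfile has no filename")
        load_resfile(self.filename).apply(task)


def read_resfile(path: str) -> TaskOperation:
    """Build a configured resfile task operation from a path (also
    validates that the file parses)."""
    load_resfile(path)
    return ReadResfile(path)


# -- residue selectors -------------------------------------------------------


class ResidueSelector:
    key_name: str = ""

    def parse_my_tag(self, tag: Tag) -> None:
        pass

    def selects(self, pose: Pose, i: int) -> bool:
        raise NotImplementedError


class ResidueIndexIs(ResidueSelector):
    key_name = "ResidueIndexIs"

    def __init__(self, indices=()):
        self.indices = set(indices)

    def parse_my_tag(self, tag):
        self.indices = set(tag.get_option_list("indices", int))

    def selects(self, pose, i):
        return i in self.indices


class ResidueHasProperty(ResidueSelector):
    key_name = "ResidueHasProperty"

    def __init__(self, prop: str | None = None):
        self.property = prop

    def parse_my_tag(self, tag):
        self.property = tag.get_option("property")

    def selects(self, pose, i):
        return self.property in pose.residue(i).properties


class ResidueLacksProperty(ResidueHasProperty):
    key_name = "ResidueLacksProperty"

    def selects(self, pose, i):
        return self.property not in pose.residue(i).properties


# -- residue-level operations ------------------------------------------------


class ResLvlTaskOperation:
    key_name: str = ""

    def parse_my_tag(self, tag: Tag) -> None:
        pass

    def apply(self, task: PackerTask, i: int) -> None:
        raise NotImplementedError


class PreventRepackingRLT(ResLvlTaskOperation):
    key_name = "PreventRepackingRLT"

    def apply(self, task, i):
        task.prevent_repacking(i)


class RestrictToRepackingRLT(ResLvlTaskOperation):
    key_name = "RestrictToRepackingRLT"

    def apply(self, task, i):
        task.restrict_to_repacking(i)


class AddBehaviorRLT(ResLvlTaskOperation):
    """Record a behavior token on selected residues.  Consumed only by
    components outside this engine; a documented no-op for the built-ins."""

    key_name = "AddBehaviorRLT"

    def __init__(self, behavior: str = ""):
        self.behavior = behavior

    def parse_my_tag(self, tag):
        self.behavior = tag.get_option("behavior", str, "AUTO")

    def apply(self, task, i):
        task.add_behavior(i, self.behavior)


_SELECTORS = {
    cls.key_name: cls
    for cls in (ResidueIndexIs, ResidueHasProperty, ResidueLacksProperty)
}
_RLTS = {
    cls.key_name: cls
    for cls in (PreventRepackingRLT, RestrictToRepackingRLT, AddBehaviorRLT)
}


class OperateOnCertainResidues(TaskOperation):
    """Apply one residue-level operation to residues picked by one selector."""

    key_name = "OperateOnCertainResidues"

    def __init__(
        self,
        selector: ResidueSelector | None = None,
        rlt: ResLvlTaskOperation | None = None,
    ):
        super().__init__()
        self.selector = selector
        self.rlt = rlt

    def parse_my_tag(self, tag, data):
        selectors, rlts = [], []
        for sub in tag.subtags:
            if sub.name in _SELECTORS:
                sel = _SELECTORS[sub.name]()
                sel.parse_my_tag(sub)
                selectors.append(sel)
            elif sub.name in _RLTS:
                rlt = _RLTS[sub.name]()
                rlt.parse_my_tag(sub)
                rlts.append(rlt)
            else:
                raise ValidationError(
                    f"<OperateOnCertainResidues> subtag <{sub.name}> is neither "
                    f"a residue selector {sorted(_SELECTORS)} nor a residue-level "
                    f"operation {sorted(_RLTS)}"
                )
        if len(selectors) != 1 or len(rlts) != 1:
            raise ValidationError(
                f"<OperateOnCertainResidues> needs exactly one selector and one "
                f"residue-level operation, got {len(selectors)} and {len(rlts)}"
            )
        self.selector = selectors[0]
        self.rlt = rlts[0]

    def apply(self, task):
        if self.selector is None or self.rlt is None:
            raise TaskError("OperateOnCertainResidues not configured")
        for i in task.residue_indices():
            if self.selector.selects(task.pose, i):
                self.rlt.apply(task, i)


class LayerDesign(TaskOperation):
    """Restrict allowed amino acids by burial layer.

    ``layer`` is an underscore-joined list of enabled layers
    (e.g. ``core_boundary_surface``).  Residues in enabled layers design
    within the layer alphabet; residues in disabled layers repack only.
    """

    key_name = "LayerDesign"

    def __init__(self, layers=("core", "boundary", "surface")):
        super().__init__()
        self.layers = set(layers)
        self._cache: tuple[int, dict] | None = None

    def parse_my_tag(self, tag, data):
        spec = tag.get_option("layer", str, "core_boundary_surface")
        layers = set(spec.split("_"))
        unknown = layers - set(LAYER_ALPHABETS)
        if unknown:
            raise ValidationError(
                f"LayerDesign layer tokens {sorted(unknown)} unknown; "
                f"choose from {sorted(LAYER_ALPHABETS)}"
            )
        self.layers = layers

    def _layers_for(self, pose: Pose) -> dict[int, str]:
        if self._cache is not None and self._cache[0] == id(pose):
            return self._cache[1]
        layers = layer_assign(pose)
        self._cache = (id(pose), layers)
        return layers

    def apply(self, task):
        layers = self._layers_for(task.pose)
        for i, layer in layers.items():
            if layer in self.layers:
                task.restrict_allowed(i, LAYER_ALPHABETS[layer])
            else:
                task.restrict_to_repacking(i)


# ---------------------------------------------------------------------------
# section parsing and registration

_BUILTIN_OPS = (
    InitializeFromCommandline,
    IncludeCurrent,
    RestrictToRepacking,
    ReadResfile,
    OperateOnCertainResidues,
    LayerDesign,
)

#: names recognized from published protocols but outside this engine
_PLACEHOLDER_OPS = ("RestrictDesignToProteinDNAInterface",)


def register_builtins(factory: Factory) -> None:
    for cls in _BUILTIN_OPS:
        factory.register(Creator(cls.key_name, cls))
    for name in _PLACEHOLDER_OPS:
        factory.register(placeholder_creator(name, "task operation"))


def parse_task_operation(tag: Tag, data: DataMap | None = None) -> TaskOperation:
    """Factory-dispatched construction + configuration of one operation."""
    op = task_operation_factory.create(tag.name)
    op.name = tag.get_option("name", str, None)
    op.parse_my_tag(tag, data)
    return op


def parse_taskoperations_block(section: Tag, data: DataMap) -> None:
    """Instantiate a TASKOPERATIONS section into the DataMap under
    ('task_operations', name)."""
    if section.name != "TASKOPERATIONS":
        raise ValidationError(f"expected <TASKOPERATIONS>, got <{section.name}>")
    for sub in section.subtags:
        op = task_operation_factory.create(sub.name)
        name = sub.get_option("name")
        op.name = name
        op.parse_my_tag(sub, data)
        data.put("task_operations", name, op)
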