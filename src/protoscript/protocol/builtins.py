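"""Registration of built-in movers and filters with the factories."""

from __future__ import annotations

from ..registry import Creator, Factory, placeholder_creator
from .filters import (
    CompoundStatement,
    DdgFilter,
    FalseFilter,
    RmsdFilter,
    SasaFilter,
    TrueFilter,
)
from .ligand import (
    FinalMinimizer,
    HighResDocker,
    InterfaceScoreCalculator,
    Rotate,
    SlideTogether,
    StartFrom,
    Translate,
)
from .montecarlo import GenericMonteCarlo, LoopOver
from .packmovers import PackRotamersMover, RepackMinimize
from .parsedprotocol import ParsedProtocol

_BUILTIN_MOVERS = (
    PackRotamersMover,
    RepackMinimize,
    GenericMonteCarlo,
    LoopOver,
    ParsedProtocol,
    StartFrom,
    Translate,
    Rotate,
    SlideTogether,
    HighResDocker,
    FinalMinimizer,
    InterfaceScoreCalculator,
)

_BUILTIN_FILTERS = (
    DdgFilter,
    SasaFilter,
    RmsdFilter,
    CompoundStatement,
    FalseFilter,
    TrueFilter,
)

#: mover names recognized from published protocols but outside this engine;
#: they register as loud placeholders and double as plugin-API demonstration
#: points (register your own creator under the name to supply them)
_PLACEHOLDER_MOVERS = (
    "Backrub",
    "Docking",
    "FlxbbDesign",
    "LoopFinder",
    "LoopRemodel",
    "AddOrRemoveMatchCsts",
    "EnzRepackMinimize",
    "DnaInterfaceMultiStateDesign",
    "DesignProteinBackboneAroundDNA",
    "DnaInterfacePacker",
)

_PLACEHOLDER_FILTERS = (
    "PackStat",
    "EnzScore",
    "LigInterfaceEnergy",
)


def register_builtins(mover_factory: Factory, filter_factory: Factory) -> None:
    for cls in _BUILTIN_MOVERS:
        mover_factory.register(Creator(cls.key_name, cls))
    for name in _PLACEHOLDER_MOVERS:
        mover_factory.register(placeholder_creator(name, "mover"))
    for cls in _BUILTIN_FILTERS:
        filter_factory.register(Creator(cls.key_name, cls))
    for name in _PLACEHOLDER_FILTERS:
        filter_factory.register(placeholder_creator(name, "filter"))
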