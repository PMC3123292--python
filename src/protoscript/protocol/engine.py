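"""Turn script text into an executable ParsedProtocol.

Sections are instantiated in dependency order regardless of where they
appear in the document -- score functions first (published scripts declare
filters that use score functions from sections appearing later, or rely on
the pre-seeded defaults), then ligand-docking auxiliary sections, task
operations, filters, movers and finally the PROTOCOLS ordering.

The DataMap only matters during this phase: components capture the handles
they need, so the returned protocol stays executable after the DataMap is
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..datamap import DataMap
from ..packing.taskops import PackerGlobals, parse_taskoperations_block
from ..registry import init_builtins
from ..structure.scorefxn import parse_scorefxns_block
from ..tagparse import ScriptModel, parse_script
from .base import Filter, Mover
from .ligand import parse_ligand_sections
from .parsedprotocol import ParsedProtocol, parse_movers_and_filters, parse_protocols

__all__ = ["ParsedScript", "parse_protocol_text"]


@dataclass
class ParsedScript:
    protocol: ParsedProtocol
    movers: dict[str, Mover]
    filters: dict[str, Filter]
    model: ScriptModel
    datamap: DataMap


def parse_protocol_text(
    text: str,
    datamap: DataMap | None = None,
    packer_globals: PackerGlobals | None = None,
) -> ParsedScript:
    """Parse and instantiate a complete protocol script."""
    init_builtins()
    model = ScriptModel(parse_script(text))
    data = datamap if datamap is not None else DataMap()
    if packer_globals is not None and not data.has("config", "packer_globals"):
        data.put("config", "packer_globals", packer_globals)
    parse_scorefxns_block(model.section("SCOREFXNS"), data)
    parse_ligand_sections(model, data)
    taskops_section = model.section("TASKOPERATIONS")
    if taskops_section is not None:
        parse_taskoperations_block(taskops_section, data)
    movers, filters = parse_movers_and_filters(model, data)
    protocol = parse_protocols(model.section("PROTOCOLS"), movers, filters)
    return ParsedScript(
        protocol=protocol, movers=movers, filters=filters, model=model, datamap=data
    )
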