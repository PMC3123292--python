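"""Bundled example protocol scripts.

These scripts exercise every part of the engine: a script skeleton, a
task-operation showcase, flexible-backbone monomer design, protein-protein
interface redesign, interface loop remodelling, enzyme design, small-
molecule docking, and protein-DNA interface design.  Several reference
components (Backrub, FlxbbDesign, the loop/enzyme/DNA machinery) that this
engine deliberately does not implement: those scripts parse cleanly at the
tag level, and instantiating them raises a recognized-but-not-implemented
error that points at the plugin API.
"""

from __future__ import annotations

from importlib import resources

__all__ = ["names", "load", "SCRIPTS"]

SCRIPTS = {
    "skeleton": "skeleton.xml",
    "taskops_excerpt": "taskops_excerpt.xml",
    "flexbb_design": "flexbb_design.xml",
    "interface_redesign": "interface_redesign.xml",
    "loop_remodel": "loop_remodel.xml",
    "enzyme_design": "enzyme_design.xml",
    "ligand_docking": "ligand_docking.xml",
    "dna_design": "dna_design.xml",
}

#: the six application scripts (excludes the skeleton and the excerpt)
APPLICATION_SCRIPTS = (
    "flexbb_design",
    "interface_redesign",
    "loop_remodel",
    "enzyme_design",
    "ligand_docking",
    "dna_design",
)


def names() -> list[str]:
    return list(SCRIPTS)


def load(name: str) -> str:
    """Return the script text by corpus name."""
    if name not in SCRIPTS:
        raise KeyError(f"unknown corpus script {name!r}; have {names()}")
    return (
        resources.files("protoscript")
        .joinpath("data")
        .joinpath("corpus")
        .joinpath(SCRIPTS[name])
        .read_text()
    )
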