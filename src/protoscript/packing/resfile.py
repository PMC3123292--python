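"""Minimal resfile dialect.

Layout::

    [default command lines]      applied to every residue
    start
    <pdbnum> <chain> <command>   per-residue lines

Commands: ``NATRO`` (freeze: no repacking), ``NATAA`` (repack only, no
design), ``ALLAA`` (no restriction) and ``PIKAA <letters>`` (restrict the
allowed amino acids to the given one-letter codes).
"""

from __future__ import annotations

import os
from dataclasses import dataclass

from ..errors import ResfileError
from ..structure import chem
from .task import PackerTask

__all__ = ["Resfile", "parse_resfile_text", "load_resfile"]

_COMMANDS = ("NATRO", "NATAA", "ALLAA", "PIKAA")


@dataclass
class _Line:
    pdb_number: int
    chain: str
    command: str
    letters: set[str]


@dataclass
class Resfile:
    default_commands: list[tuple[str, set[str]]]
    lines: list[_Line]

    def apply(self, task: PackerTask) -> None:
        pose = task.pose
        for command, letters in self.default_commands:
            for i, res in pose.residues():
                if res.is_protein:
                    _apply_command(task, i, command, letters)
        for line in self.lines:
            i = pose.find_residue(line.pdb_number, line.chain)
            if i is None:
                raise ResfileError(
                    f"resfile refers to residue {line.chain} {line.pdb_number}, "
                    f"absent from the pose"
                )
            _apply_command(task, i, line.command, line.letters)


def _apply_command(task: PackerTask, i: int, command: str, letters: set[str]) -> None:
    if command == "NATRO":
        task.prevent_repacking(i)
    elif command == "NATAA":
        task.restrict_to_repacking(i)
    elif command == "ALLAA":
        pass
    elif command == "PIKAA":
        task.restrict_allowed(i, letters)
    else:  # pragma: no cover - guarded at parse
        raise ResfileError(f"unknown resfile command {command!r}")


def _parse_command(tokens: list[str], lineno: int) -> tuple[str, set[str]]:
    command = tokens[0].upper()
    if command not in _COMMANDS:
        raise ResfileError(f"line {lineno}: unknown resfile command {tokens[0]!r}")
    letters: set[str] = set()
    if command == "PIKAA":
        if len(tokens) < 2:
            raise ResfileError(f"line {lineno}: PIKAA needs amino-acid letters")
        letters = set("".join(tokens[1:]).upper())
        bad = letters - chem.ALL_LETTERS
        if bad:
            raise ResfileError(
                f"line {lineno}: PIKAA letters {sorted(bad)} are not amino acids"
            )
    elif len(tokens) > 1:
        raise ResfileError(f"line {lineno}: unexpected text after {command}")
    return command, letters


def parse_resfile_text(text: str) -> Resfile:
    defaults: list[tuple[str, set[str]]] = []
    lines: list[_Line] = []
    seen_start = False
    for lineno, raw in enumerate(text.splitlines(), 1):
        stripped = raw.split("#", 1)[0].strip()
        if not stripped:
            continue
        tokens = stripped.split()
        if not seen_start:
            if tokens[0].lower() == "start":
                seen_start = True
                continue
            defaults.append(_parse_command(tokens, lineno))
            continue
        if len(tokens) < 3:
            raise ResfileError(
                f"line {lineno}: expected '<pdbnum> <chain> <command>'"
            )
        try:
            pdb_number = int(tokens[0])
        except ValueError:
            raise ResfileError(
                f"line {lineno}: residue number {tokens[0]!r} is not an integer"
            ) from None
        chain = tokens[1]
        command, letters = _parse_command(tokens[2:], lineno)
        lines.append(_Line(pdb_number, chain, command, letters))
    return Resfile(defaults, lines)


def load_resfile(path: str | os.PathLike) -> Resfile:
    path = os.fspath(path)
    if not os.path.exists(path):
        raise ResfileError(f"no such resfile: {path}")
    with open(path) as fh:
        return parse_resfile_text(fh.read())
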