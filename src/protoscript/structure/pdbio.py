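"""PDB reading and writing for the reduced residue representation.

Reading honours ATOM/HETATM/TER/END records.  HETATM residues become LIGAND
residues carrying their atoms verbatim; for protein residues the four
backbone atoms are kept and all other heavy atoms are collapsed to their
mean, the side-chain centroid.  Only the blank/'A' alternate location is
kept.  Writing emits backbone atoms plus the centroid as the pseudo-atom
``SCC`` in fixed-column PDB format.

Parsing of the fixed-column records is delegated to gemmi after a light
validation pass that reports malformed ATOM/HETATM lines with their line
number (gemmi itself is forgiving about them).
"""

from __future__ import annotations

import os

import gemmi
import numpy as np

from ..errors import PDBFormatError, StructureError
from . import chem
from .pose import BACKBONE_ATOMS, LIGAND, POLAR, PROTEIN, Pose, Residue

__all__ = ["read_pdb", "write_pdb"]


def _validate_columns(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise PDBFormatError(
                f"ATOM/HETATM record shorter than 54 columns", line=lineno
            )
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            fieldtext = line[lo:hi].strip()
            try:
                float(fieldtext)
            except ValueError:
                raise PDBFormatError(
                    f"malformed {what} coordinate field {fieldtext!r}", line=lineno
                ) from None


def read_pdb(path: str | os.PathLike) -> Pose:
    """Read a PDB file into a Pose (and snapshot its starting coordinates)."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise StructureError(f"no such PDB file: {path}")
    with open(path) as fh:
        text = fh.read()
    _validate_columns(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise StructureError(f"{path}: no model records")
    model = st[0]
    residues: list[Residue] = []
    seen: set[tuple[str, int, str]] = set()
    for chain in model:
        for res in chain:
            key = (chain.name, res.seqid.num, res.seqid.icode or " ")
            atoms: dict[str, np.ndarray] = {}
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    continue
                if atom.element == gemmi.Element("H"):
                    continue
                atoms[atom.name] = np.array(
                    [atom.pos.x, atom.pos.y, atom.pos.z], dtype=float
                )
            if not atoms:
                continue
            if key in seen:
                raise PDBFormatError(
                    f"duplicate residue {chain.name}{res.seqid.num} in {path}"
                )
            seen.add(key)
            het = res.het_flag == "H" or res.name not in chem.NAME3_TO_LETTER
            if het:
                residues.append(
                    Residue(
                        name3=res.name,
                        chain_id=chain.name,
                        pdb_number=res.seqid.num,
                        atoms=atoms,
                        properties={LIGAND},
                    )
                )
                continue
            missing = [a for a in BACKBONE_ATOMS if a not in atoms]
            if missing:
                raise PDBFormatError(
                    f"residue {chain.name}{res.seqid.num} ({res.name}) missing "
                    f"backbone atoms {missing}"
                )
            side = [
                pos
                for name, pos in atoms.items()
                if name not in BACKBONE_ATOMS
            ]
            if side:
                centroid = np.mean(np.asarray(side), axis=0)
            else:
                centroid = atoms["CA"].copy()
            letter = chem.NAME3_TO_LETTER[res.name]
            props = {PROTEIN}
            if chem.AMINO_ACIDS[letter].polar:
                props.add(POLAR)
            residues.append(
                Residue(
                    name3=res.name,
                    chain_id=chain.name,
                    pdb_number=res.seqid.num,
                    atoms={a: atoms[a] for a in BACKBONE_ATOMS},
                    centroid=centroid,
                    properties=props,
                )
            )
    if not residues:
        raise StructureError(f"{path}: zero residues")
    pose = Pose(residues, provenance={"path": path})
    pose.take_snapshot()
    return pose


def write_pdb(pose: Pose, path: str | os.PathLike) -> None:
    """Write a pose in fixed-column PDB format (backbone + SCC centroid)."""
    st = gemmi.Structure()
    st.name = "pose"
    model = gemmi.Model("1")
    for chain_id in pose.chains():
        chain = gemmi.Chain(chain_id)
        for i in pose.chain_indices(chain_id):
            res = pose.residue(i)
            gres = gemmi.Residue()
            gres.name = res.name3
            gres.seqid = gemmi.SeqId(res.pdb_number, " ")
            gres.het_flag = "H" if res.is_ligand else "A"
            if res.is_ligand:
                items = list(res.atoms.items())
            else:
                items = [(a, res.atoms[a]) for a in BACKBONE_ATOMS]
                if res.centroid is not None:
                    items.append(("SCC", res.centroid))
            for name, xyz in items:
                atom = gemmi.Atom()
                atom.name = name
                atom.pos = gemmi.Position(*map(float, xyz))
                atom.occ = 1.0
                atom.b_iso = 0.0
                element = name[0] if name[0] in ("N", "C", "O", "S") else "C"
                if name == "SCC":
                    element = "C"
                atom.element = gemmi.Element(element)
                gres.add_atom(atom)
            chain.add_residue(gres)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True, numbered_ter=False))
    with open(os.fspath(path), "w") as fh:
        fh.write(doc)
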