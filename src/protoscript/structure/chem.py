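"""Reduced-representation chemistry tables.

Each amino acid is a rigid backbone (N, CA, C, O) plus one side-chain
centroid sphere.  The centroid radius, its distance from CA, the POLAR flag
and a coarse partial charge are fixed per amino-acid type by the table
below.  The values are deliberately schematic -- bulky side chains get
larger radii and longer CA-centroid arms, charged side chains carry +/-1 --
and make no claim of physical accuracy; they exist so that packing,
docking and filtering have a deterministic, desk-scale energy landscape.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AminoAcid",
    "AMINO_ACIDS",
    "NAME3_TO_LETTER",
    "LETTERS",
    "ALL_LETTERS",
    "BACKBONE_RADII",
    "BACKBONE_CHARGES",
    "LIGAND_ATOM_RADIUS",
    "LIGAND_ATOM_CHARGE",
]


@dataclass(frozen=True)
class AminoAcid:
    letter: str
    name3: str
    polar: bool
    centroid_radius: float  # Angstrom
    ca_centroid_distance: float  # Angstrom
    charge: float  # dimensionless


_TABLE = [
    #       letter name3  polar  radius  dist  charge
    AminoAcid("A", "ALA", False, 1.8, 1.5, 0.0),
    AminoAcid("C", "CYS", False, 2.0, 2.0, 0.0),
    AminoAcid("D", "ASP", True, 2.2, 2.5, -1.0),
    AminoAcid("E", "GLU", True, 2.4, 3.0, -1.0),
    AminoAcid("F", "PHE", False, 2.8, 3.4, 0.0),
    AminoAcid("G", "GLY", False, 1.0, 0.0, 0.0),
    AminoAcid("H", "HIS", True, 2.6, 3.0, 0.25),
    AminoAcid("I", "ILE", False, 2.4, 2.3, 0.0),
    AminoAcid("K", "LYS", True, 2.6, 3.5, 1.0),
    AminoAcid("L", "LEU", False, 2.4, 2.6, 0.0),
    AminoAcid("M", "MET", False, 2.5, 2.9, 0.0),
    AminoAcid("N", "ASN", True, 2.2, 2.5, 0.0),
    AminoAcid("P", "PRO", False, 1.9, 1.9, 0.0),
    AminoAcid("Q", "GLN", True, 2.4, 3.0, 0.0),
    AminoAcid("R", "ARG", True, 2.9, 4.0, 1.0),
    AminoAcid("S", "SER", True, 1.9, 1.9, 0.0),
    AminoAcid("T", "THR", True, 2.1, 1.9, 0.0),
    AminoAcid("V", "VAL", False, 2.2, 2.0, 0.0),
    AminoAcid("W", "TRP", False, 3.0, 3.9, 0.0),
    AminoAcid("Y", "TYR", True, 2.9, 3.8, 0.0),
]

AMINO_ACIDS: dict[str, AminoAcid] = {aa.letter: aa for aa in _TABLE}
NAME3_TO_LETTER: dict[str, str] = {aa.name3: aa.letter for aa in _TABLE}
LETTERS = "".join(sorted(AMINO_ACIDS))
ALL_LETTERS = frozenset(AMINO_ACIDS)

# backbone interaction-site parameters (shared by all amino acids)
BACKBONE_RADII = {"N": 1.55, "CA": 1.70, "C": 1.70, "O": 1.52}
BACKBONE_CHARGES = {"N": -0.35, "CA": 0.10, "C": 0.45, "O": -0.40}

# defaults for generic ligand atoms
LIGAND_ATOM_RADIUS = 2.0
LIGAND_ATOM_CHARGE = 0.0
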