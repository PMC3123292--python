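"""Toy macromolecular data model.

A :class:`Pose` is an ordered list of residues (pose numbering 1..n) grouped
into chains.  Protein residues carry the four backbone atoms plus one
side-chain centroid; ligand residues carry a set of generic atoms.  The pose
remembers a starting-coordinates snapshot (for RMSD and travel measures),
the provenance of its coordinates, and the accumulated rigid-body transform
applied to each chain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from ..errors import StructureError
from . import chem

__all__ = ["Residue", "Pose", "PROTEIN", "DNA", "LIGAND", "POLAR"]

PROTEIN = "PROTEIN"
DNA = "DNA"
LIGAND = "LIGAND"
POLAR = "POLAR"

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class Residue:
    """One residue: either protein (backbone + centroid) or ligand (atoms)."""

    name3: str
    chain_id: str
    pdb_number: int
    atoms: dict[str, np.ndarray]
    centroid: np.ndarray | None = None
    properties: set = field(default_factory=set)
    # per-atom radii/charges for ligand residues (defaults used when absent)
    atom_radii: dict[str, float] = field(default_factory=dict)
    atom_charges: dict[str, float] = field(default_factory=dict)

    @property
    def is_ligand(self) -> bool:
        return LIGAND in self.properties

    @property
    def is_protein(self) -> bool:
        return PROTEIN in self.properties

    @property
    def letter(self) -> str | None:
        return chem.NAME3_TO_LETTER.get(self.name3)

    @property
    def amino_acid(self) -> chem.AminoAcid | None:
        letter = self.letter
        return chem.AMINO_ACIDS[letter] if letter else None

    def sites(self) -> Iterator[tuple[str, np.ndarray, float, float]]:
        """Yield (name, position, radius, charge) for every interaction site."""
        if self.is_ligand:
            for name, pos in self.atoms.items():
                yield (
                    name,
                    pos,
                    self.atom_radii.get(name, chem.LIGAND_ATOM_RADIUS),
                    self.atom_charges.get(name, chem.LIGAND_ATOM_CHARGE),
                )
        else:
            for name in BACKBONE_ATOMS:
                yield (
                    name,
                    self.atoms[name],
                    chem.BACKBONE_RADII[name],
                    chem.BACKBONE_CHARGES[name],
                )
            aa = self.amino_acid
            if self.centroid is not None and aa is not None:
                yield ("SCC", self.centroid, aa.centroid_radius, aa.charge)

    def copy(self) -> "Residue":
        return Residue(
            name3=self.name3,
            chain_id=self.chain_id,
            pdb_number=self.pdb_number,
            atoms={k: v.copy() for k, v in self.atoms.items()},
            centroid=None if self.centroid is None else self.centroid.copy(),
            properties=set(self.properties),
            atom_radii=dict(self.atom_radii),
            atom_charges=dict(self.atom_charges),
        )


def _validate_finite(res: Residue) -> None:
    for _, pos, _, _ in res.sites():
        if not np.all(np.isfinite(pos)):
            raise StructureError(
                f"non-finite coordinate in residue {res.chain_id}{res.pdb_number}"
            )


class Pose:
    """Ordered residues with 1-based pose numbering and chain structure."""

    def __init__(self, residues: list[Residue], provenance: dict | None = None):
        self._residues = list(residues)
        for res in self._residues:
            _validate_finite(res)
        self.provenance: dict = dict(provenance or {})
        self.start_coords: dict[int, dict[str, np.ndarray]] | None = None
        #: per-trajectory random source, set by the executor; not copied deeply
        self.rng: np.random.Generator | None = None
        #: accumulated per-chain rigid transform (R, t) since creation
        self.chain_transforms: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    # -- residue access --------------------------------------------------

    def __len__(self) -> int:
        return len(self._residues)

    def residue(self, i: int) -> Residue:
        """1-based pose-numbered access."""
        if not 1 <= i <= len(self._residues):
            raise StructureError(f"pose index {i} out of range 1..{len(self._residues)}")
        return self._residues[i - 1]

    def residues(self) -> Iterator[tuple[int, Residue]]:
        for i, res in enumerate(self._residues, 1):
            yield i, res

    def chains(self) -> list[str]:
        seen: list[str] = []
        for res in self._residues:
            if res.chain_id not in seen:
                seen.append(res.chain_id)
        return seen

    def chain_indices(self, chain_id: str) -> list[int]:
        return [i for i, r in self.residues() if r.chain_id == chain_id]

    def is_ligand_chain(self, chain_id: str) -> bool:
        idx = self.chain_indices(chain_id)
        return bool(idx) and all(self.residue(i).is_ligand for i in idx)

    def find_residue(self, pdb_number: int, chain_id: str) -> int | None:
        for i, res in self.residues():
            if res.pdb_number == pdb_number and res.chain_id == chain_id:
                return i
        return None

    def sequence(self) -> str:
        return "".join(r.letter or "x" for r in self._residues if r.is_protein)

    # -- copies and snapshots -------------------------------------------

    def copy(self) -> "Pose":
        """Deep copy of coordinates/identities; the rng handle and the
        starting snapshot are shared with the original."""
        other = Pose([r.copy() for r in self._residues], provenance=self.provenance)
        other.start_coords = self.start_coords
        other.rng = self.rng
        other.chain_transforms = {
            c: (R.copy(), t.copy()) for c, (R, t) in self.chain_transforms.items()
        }
        return other

    def assign(self, other: "Pose") -> None:
        """Overwrite this pose's residues/transforms with a copy of
        ``other``'s (in-place update used by movers)."""
        self._residues = [r.copy() for r in other._residues]
        self.chain_transforms = {
            c: (R.copy(), t.copy()) for c, (R, t) in other.chain_transforms.items()
        }
        self.start_coords = other.start_coords
        self.provenance = dict(other.provenance)

    def take_snapshot(self) -> None:
        """Record current coordinates as the starting structure."""
        snap: dict[int, dict[str, np.ndarray]] = {}
        for i, res in self.residues():
            coords = {k: v.copy() for k, v in res.atoms.items()}
            if res.centroid is not None:
                coords["SCC"] = res.centroid.copy()
            snap[i] = coords
        self.start_coords = snap

    def all_coords(self) -> np.ndarray:
        """All site coordinates stacked (for cheap identity checks)."""
        rows = [pos for _, res in self.residues() for _, pos, _, _ in res.sites()]
        return np.asarray(rows, dtype=float)

    def ca_coords(self, subset: list[int] | None = None) -> np.ndarray:
        indices = subset if subset is not None else [
            i for i, r in self.residues() if r.is_protein
        ]
        return np.asarray([self.residue(i).atoms["CA"] for i in indices], dtype=float)

    # -- geometry --------------------------------------------------------

    def chain_centroid(self, chain_id: str) -> np.ndarray:
        coords = [
            pos
            for i in self.chain_indices(chain_id)
            for _, pos, _, _ in self.residue(i).sites()
        ]
        if not coords:
            raise StructureError(f"no chain {chain_id!r} in pose")
        return np.mean(np.asarray(coords), axis=0)

    def translate_chain(self, chain_id: str, vec: np.ndarray) -> None:
        self.transform_chain(chain_id, np.eye(3), np.asarray(vec, dtype=float))

    def transform_chain(
        self, chain_id: str, R: np.ndarray, t: np.ndarray
    ) -> None:
        """Apply x -> R x + t to every site of one chain and accumulate the
        chain's rigid transform."""
        idx = self.chain_indices(chain_id)
        if not idx:
            raise StructureError(f"no chain {chain_id!r} in pose")
        R = np.asarray(R, dtype=float)
        t = np.asarray(t, dtype=float)
        for i in idx:
            res = self.residue(i)
            for name in res.atoms:
                res.atoms[name] = R @ res.atoms[name] + t
            if res.centroid is not None:
                res.centroid = R @ res.centroid + t
        R0, t0 = self.chain_transforms.get(chain_id, (np.eye(3), np.zeros(3)))
        self.chain_transforms[chain_id] = (R @ R0, R @ t0 + t)

    def rotate_chain_about(
        self, chain_id: str, R: np.ndarray, center: np.ndarray
    ) -> None:
        center = np.asarray(center, dtype=float)
        self.transform_chain(chain_id, R, center - np.asarray(R) @ center)

    # -- subsets and identity changes -----------------------------------

    def subpose(self, chain_ids: list[str]) -> "Pose":
        residues = [
            r.copy() for r in self._residues if r.chain_id in set(chain_ids)
        ]
        if not residues:
            raise StructureError(f"no residues in chains {chain_ids}")
        sub = Pose(residues, provenance=self.provenance)
        sub.take_snapshot()
        return sub

    def set_residue_identity(self, i: int, letter: str) -> None:
        """Mutate a protein residue to another amino-acid type (backbone and
        centroid position unchanged; radius/charge/polarity follow the type)."""
        res = self.residue(i)
        if not res.is_protein:
            raise StructureError(f"residue {i} is not protein")
        aa = chem.AMINO_ACIDS.get(letter)
        if aa is None:
            raise StructureError(f"unknown amino-acid letter {letter!r}")
        res.name3 = aa.name3
        res.properties.discard(POLAR)
        if aa.polar:
            res.properties.add(POLAR)

    # -- site arrays for scoring ----------------------------------------

    def site_arrays(self):
        """Flattened site table: (positions (m,3), radii (m,), charges (m,),
        residue pose index (m,), chain code (m,))."""
        pos, rad, chg, ridx, cidx = [], [], [], [], []
        chain_code = {c: k for k, c in enumerate(self.chains())}
        for i, res in self.residues():
            code = chain_code[res.chain_id]
            for _, p, r, q in res.sites():
                pos.append(p)
                rad.append(r)
                chg.append(q)
                ridx.append(i)
                cidx.append(code)
        return (
            np.asarray(pos, dtype=float),
            np.asarray(rad, dtype=float),
            np.asarray(chg, dtype=float),
            np.asarray(ridx, dtype=int),
            np.asarray(cidx, dtype=int),
        )

    def __repr__(self):
        return (
            f"Pose({len(self)} residues, chains={self.chains()}, "
            f"provenance={self.provenance.get('kind') or self.provenance.get('path')})"
        )
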