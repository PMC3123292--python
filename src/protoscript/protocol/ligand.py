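"""Rigid-body small-molecule docking movers and their auxiliary sections.

The docking movers operate on a designated ligand chain: StartFrom places
it at given coordinates, Translate/Rotate search for clash-free/contacting
placements, SlideTogether brings the partners into contact, HighResDocker
couples small rigid perturbations with repacking, FinalMinimizer performs
rigid-body minimisation, and InterfaceScoreCalculator reports per-term
interface scores and ligand descriptors.

LIGAND_AREAS describe per-ligand interface rules (cutoff distance, whether
the residue's own centroid radius extends the cutoff, whether distances
are measured to every ligand atom or only the ligand centroid);
INTERFACE_BUILDERS turn areas into residue sets; MOVEMAP_BUILDERS combine
side-chain and backbone interfaces into a MoveMap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from ..datamap import DataMap
from ..errors import ProtocolError, StructureError
from ..packing.annealer import pack_anneal, rotamer_trials
from ..packing.task import default_task
from ..structure.pose import Pose
from ..structure.rmsd import rmsd_no_superposition
from ..structure.scorefxn import ScoreFunction, raw_terms_between, score
from ..tagparse import Tag
from .base import Mover, Status, pose_rng
from .minimize import minimize_pose
from .movemap import MoveMap

__all__ = [
    "LigandArea",
    "InterfaceBuilder",
    "MoveMapBuilder",
    "parse_ligand_sections",
    "StartFrom",
    "Translate",
    "Rotate",
    "SlideTogether",
    "HighResDocker",
    "FinalMinimizer",
    "InterfaceScoreCalculator",
    "start_from",
    "translate",
    "rotate",
    "slide_together",
    "ligand_is_clashing",
]

# documented defaults where published protocols say "a threshold"/"slightly"
ROTATE_REP_MAX = 10.0  # raw repulsion ceiling for an accepted rotation
ROTATE_ATR_MIN = -0.1  # raw attraction ceiling (requires some contact)
SLIDE_STEP = 0.5  # A, approach step
SLIDE_BACKSTEP = 0.25  # A, back-off step after the first clash
HIGH_RES_ANGSTROM = 0.1  # A, translation magnitude per docking cycle
HIGH_RES_DEGREES = 2.8  # deg, rotation magnitude per docking cycle
HIGH_RES_TEMPERATURE = 0.6
UNBOUND_SHIFT = np.array([500.0, 0.0, 0.0])


# ---------------------------------------------------------------------------
# auxiliary sections


@dataclass
class LigandArea:
    name: str
    chain: str
    cutoff: float = 6.0
    add_nbr_radius: bool = False
    all_atom_mode: bool = False
    minimize_ligand: float = 0.0  # recorded; no internal ligand DOFs here
    calpha_restraints: float = 0.0

    @classmethod
    def from_tag(cls, tag: Tag) -> "LigandArea":
        return cls(
            name=tag.name,
            chain=tag.get_option("chain"),
            cutoff=tag.get_option("cutoff", float, 6.0),
            add_nbr_radius=tag.get_option("add_nbr_radius", bool, False),
            all_atom_mode=tag.get_option("all_atom_mode", bool, False),
            minimize_ligand=tag.get_option("minimize_ligand", float, 0.0),
            calpha_restraints=tag.get_option("Calpha_restraints", float, 0.0),
        )

    def interface_residues(self, pose: Pose) -> set[int]:
        lig_idx = pose.chain_indices(self.chain)
        if not lig_idx:
            raise StructureError(f"ligand area {self.name!r}: no chain {self.chain!r}")
        if self.all_atom_mode:
            ref = np.asarray(
                [
                    pos
                    for i in lig_idx
                    for _, pos, _, _ in pose.residue(i).sites()
                ]
            )
        else:
            ref = pose.chain_centroid(self.chain)[None, :]
        out: set[int] = set()
        for i, res in pose.residues():
            if not res.is_protein:
                continue
            point = res.centroid if res.centroid is not None else res.atoms["CA"]
            cutoff = self.cutoff
            if self.add_nbr_radius and res.amino_acid is not None:
                cutoff += res.amino_acid.centroid_radius
            if np.min(np.linalg.norm(ref - point, axis=1)) <= cutoff:
                out.add(i)
        return out


@dataclass
class InterfaceBuilder:
    name: str
    areas: list[LigandArea]
    extension_window: int = 0

    def build(self, pose: Pose) -> set[int]:
        residues: set[int] = set()
        for area in self.areas:
            residues |= area.interface_residues(pose)
        if self.extension_window:
            widened = set(residues)
            for i in residues:
                chain = pose.residue(i).chain_id
                for j in range(i - self.extension_window, i + self.extension_window + 1):
                    if 1 <= j <= len(pose) and pose.residue(j).chain_id == chain:
                        widened.add(j)
            residues = widened
        return residues

    def ligand_chains(self) -> set[str]:
        return {a.chain for a in self.areas}

    def max_calpha(self) -> float:
        return max((a.calpha_restraints for a in self.areas), default=0.0)


@dataclass
class MoveMapBuilder:
    name: str
    sc_interface: InterfaceBuilder | None = None
    bb_interface: InterfaceBuilder | None = None
    minimize_water: bool = False  # recorded; no waters in the reduced model

    def build(self, pose: Pose) -> MoveMap:
        movemap = MoveMap()
        if self.sc_interface is not None:
            movemap.sc = self.sc_interface.build(pose)
            movemap.rb_chains |= self.sc_interface.ligand_chains()
        if self.bb_interface is not None:
            movemap.bb = self.bb_interface.build(pose)
            movemap.rb_chains |= self.bb_interface.ligand_chains()
            movemap.calpha_restraints = self.bb_interface.max_calpha()
        return movemap


def parse_ligand_sections(model, data: DataMap) -> None:
    """Instantiate LIGAND_AREAS / INTERFACE_BUILDERS / MOVEMAP_BUILDERS
    (in that dependency order) into the DataMap; the subtag name is the
    instance name."""
    areas_section = model.extra_section("LIGAND_AREAS")
    if areas_section is not None:
        for sub in areas_section.subtags:
            data.put("ligand_areas", sub.name, LigandArea.from_tag(sub))
    builders_section = model.extra_section("INTERFACE_BUILDERS")
    if builders_section is not None:
        for sub in builders_section.subtags:
            names = sub.get_option_list("ligand_areas", str)
            areas = [data.get("ligand_areas", n, LigandArea) for n in names]
            data.put(
                "interface_builders",
                sub.name,
                InterfaceBuilder(
                    sub.name, areas, sub.get_option("extension_window", int, 0)
                ),
            )
    movemap_section = model.extra_section("MOVEMAP_BUILDERS")
    if movemap_section is not None:
        for sub in movemap_section.subtags:
            sc_name = sub.get_option("sc_interface", str, None)
            bb_name = sub.get_option("bb_interface", str, None)
            data.put(
                "movemap_builders",
                sub.name,
                MoveMapBuilder(
                    sub.name,
                    sc_interface=(
                        data.get("interface_builders", sc_name, InterfaceBuilder)
                        if sc_name
                        else None
                    ),
                    bb_interface=(
                        data.get("interface_builders", bb_name, InterfaceBuilder)
                        if bb_name
                        else None
                    ),
                    minimize_water=sub.get_option("minimize_water", bool, False),
                ),
            )


# ---------------------------------------------------------------------------
# functional docking operations


def _require_ligand_chain(pose: Pose, chain: str) -> None:
    if chain not in pose.chains():
        raise StructureError(f"no chain {chain!r} in pose")
    if not pose.is_ligand_chain(chain):
        raise StructureError(f"chain {chain!r} is not a ligand chain")


def ligand_is_clashing(pose: Pose, chain: str) -> bool:
    """Clash <=> positive raw repulsion between the ligand and the rest."""
    lig = pose.chain_indices(chain)
    rest = [i for i, _ in pose.residues() if i not in set(lig)]
    return raw_terms_between(pose, lig, rest)["rep"] > 0.0


def _ligand_raw(pose: Pose, chain: str) -> dict[str, float]:
    lig = pose.chain_indices(chain)
    rest = [i for i, _ in pose.residues() if i not in set(lig)]
    return raw_terms_between(pose, lig, rest)


def start_from(pose: Pose, chain: str, coordinates) -> None:
    """Translate the ligand chain so its centroid sits at ``coordinates``."""
    _require_ligand_chain(pose, chain)
    target = np.asarray(coordinates, dtype=float)
    pose.translate_chain(chain, target - pose.chain_centroid(chain))


def translate(
    pose: Pose,
    chain: str,
    distribution: str,
    angstroms: float,
    cycles: int,
    rng,
) -> Status:
    """Random rigid translation re-tried until the ligand does not clash.

    Each attempt displaces the ligand from its *starting* position along a
    uniform random direction by U(0, angstroms) (or |N(0, angstroms)| for
    the gaussian distribution); the first clash-free placement is kept.
    All ``cycles`` attempts clashing restores the start and fails the
    trajectory.
    """
    _require_ligand_chain(pose, chain)
    if cycles < 1:
        raise ProtocolError("Translate cycles must be >= 1")
    rng = np.random.default_rng(rng)
    origin = pose.chain_centroid(chain)
    for _ in range(cycles):
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        if distribution == "uniform":
            magnitude = rng.uniform(0.0, angstroms)
        elif distribution == "gaussian":
            magnitude = abs(rng.normal(0.0, angstroms))
        else:
            raise ProtocolError(f"unknown distribution {distribution!r}")
        target = origin + magnitude * direction
        pose.translate_chain(chain, target - pose.chain_centroid(chain))
        if not ligand_is_clashing(pose, chain):
            return Status.SUCCESS
    pose.translate_chain(chain, origin - pose.chain_centroid(chain))
    return Status.FAIL_RETRY


def rotate(
    pose: Pose,
    chain: str,
    distribution: str,
    degrees: float,
    cycles: int,
    rng,
    rep_max: float = ROTATE_REP_MAX,
    atr_min: float = ROTATE_ATR_MIN,
) -> Status:
    """Random rigid reorientation about the ligand centroid, re-tried until
    the ligand-protein raw repulsion is at most ``rep_max`` *and* the raw
    attraction is at most ``atr_min`` (i.e. some contact exists)."""
    _require_ligand_chain(pose, chain)
    if cycles < 1:
        raise ProtocolError("Rotate cycles must be >= 1")
    rng = np.random.default_rng(rng)
    start = pose.copy()
    for _ in range(cycles):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        if distribution == "uniform":
            angle = rng.uniform(0.0, np.deg2rad(degrees))
        elif distribution == "gaussian":
            angle = min(abs(rng.normal(0.0, np.deg2rad(degrees))), np.deg2rad(degrees))
        else:
            raise ProtocolError(f"unknown distribution {distribution!r}")
        pose.assign(start)
        center = pose.chain_centroid(chain)
        pose.rotate_chain_about(
            chain, Rotation.from_rotvec(angle * axis).as_matrix(), center
        )
        raw = _ligand_raw(pose, chain)
        if raw["rep"] <= rep_max and raw["atr"] <= atr_min:
            return Status.SUCCESS
    pose.assign(start)
    return Status.FAIL_RETRY


def slide_together(pose: Pose, chain: str) -> None:
    """Advance the ligand toward the protein centroid in 0.5 A steps until
    the first clash, then back off in 0.25 A steps until clash-free."""
    _require_ligand_chain(pose, chain)
    if ligand_is_clashing(pose, chain):
        raise ProtocolError(
            "SlideTogether: partners already clash; Translate the ligand first"
        )
    lig_centroid = pose.chain_centroid(chain)
    rest = [c for c in pose.chains() if c != chain]
    protein_centroid = np.mean(
        [pose.chain_centroid(c) for c in rest], axis=0
    )
    axis = protein_centroid - lig_centroid
    norm = np.linalg.norm(axis)
    if norm < 1e-9:
        raise ProtocolError("SlideTogether: centroids coincide")
    axis /= norm
    for _ in range(100000):
        pose.translate_chain(chain, SLIDE_STEP * axis)
        if ligand_is_clashing(pose, chain):
            break
    else:
        raise ProtocolError("SlideTogether: partners never collided")
    while ligand_is_clashing(pose, chain):
        pose.translate_chain(chain, -SLIDE_BACKSTEP * axis)


# ---------------------------------------------------------------------------
# movers


class StartFrom(Mover):
    """Move a small molecule to a specified XYZ coordinate."""

    key_name = "StartFrom"

    def __init__(self, chain: str | None = None, coordinates=None):
        super().__init__()
        self.chain = chain
        self.coordinates = coordinates

    def parse_my_tag(self, tag, data, filters, movers):
        self.chain = tag.get_option("chain")
        coords = tag.get_tags("Coordinates")
        if len(coords) != 1:
            raise ProtocolError(
                f"StartFrom needs exactly one <Coordinates> subtag, got {len(coords)}"
            )
        self.coordinates = np.array(
            [coords[0].get_option(k, float) for k in ("x", "y", "z")]
        )

    def apply(self, pose) -> Status:
        start_from(pose, self.chain, self.coordinates)
        return Status.SUCCESS


class Translate(Mover):
    key_name = "Translate"

    def __init__(self, chain=None, distribution="uniform", angstroms=1.0, cycles=50):
        super().__init__()
        self.chain = chain
        self.distribution = distribution
        self.angstroms = angstroms
        self.cycles = cycles

    def parse_my_tag(self, tag, data, filters, movers):
        self.chain = tag.get_option("chain")
        self.distribution = tag.get_option("distribution", str, "uniform")
        self.angstroms = tag.get_option("angstroms", float)
        self.cycles = tag.get_option("cycles", int, 50)

    def apply(self, pose) -> Status:
        return translate(
            pose, self.chain, self.distribution, self.angstroms, self.cycles,
            pose_rng(pose),
        )


class Rotate(Mover):
    key_name = "Rotate"

    def __init__(self, chain=None, distribution="uniform", degrees=360.0, cycles=1000):
        super().__init__()
        self.chain = chain
        self.distribution = distribution
        self.degrees = degrees
        self.cycles = cycles

    def parse_my_tag(self, tag, data, filters, movers):
        self.chain = tag.get_option("chain")
        self.distribution = tag.get_option("distribution", str, "uniform")
        self.degrees = tag.get_option("degrees", float)
        self.cycles = tag.get_option("cycles", int, 1000)

    def apply(self, pose) -> Status:
        return rotate(
            pose, self.chain, self.distribution, self.degrees, self.cycles,
            pose_rng(pose),
        )


class SlideTogether(Mover):
    key_name = "SlideTogether"

    def __init__(self, chain=None):
        super().__init__()
        self.chain = chain

    def parse_my_tag(self, tag, data, filters, movers):
        self.chain = tag.get_option("chain")

    def apply(self, pose) -> Status:
        slide_together(pose, self.chain)
        return Status.SUCCESS


class HighResDocker(Mover):
    """Cycles of small rigid ligand perturbations coupled to repacking:
    a full anneal every Nth cycle and a greedy rotamer-trials pass
    otherwise, each cycle Metropolis-accepted on the score total."""

    key_name = "HighResDocker"

    def __init__(
        self,
        chains=(),
        cycles: int = 6,
        repack_every_nth: int = 3,
        sfx: ScoreFunction | None = None,
        movemap_builder: MoveMapBuilder | None = None,
    ):
        super().__init__()
        self.chains = list(chains)
        self.cycles = cycles
        self.repack_every_nth = repack_every_nth
        self.sfx = sfx
        self.movemap_builder = movemap_builder
        self.n_full_repacks = 0
        self.n_rotamer_trials = 0

    def parse_my_tag(self, tag, data, filters, movers):
        self.chains = tag.get_option_list("chains", str)
        self.cycles = tag.get_option("cycles", int, 6)
        self.repack_every_nth = tag.get_option("repack_every_Nth", int, 3)
        self.sfx = data.get(
            "scorefxns", tag.get_option("scorefxn", str, "ligand_soft_rep"), ScoreFunction
        )
        builder = tag.get_option("movemap_builder", str, None)
        if builder is not None:
            self.movemap_builder = data.get("movemap_builders", builder, MoveMapBuilder)

    def _interface_task(self, pose, movemap: MoveMap):
        task = default_task(pose)
        allowed = movemap.sc if movemap.sc else None
        for i in task.residue_indices():
            task.restrict_to_repacking(i)
            if allowed is not None and i not in allowed:
                task.prevent_repacking(i)
        task.set_include_current()
        return task

    def apply(self, pose) -> Status:
        lig_chains = [c for c in self.chains if c in pose.chains()]
        if not lig_chains or not all(pose.is_ligand_chain(c) for c in lig_chains):
            raise StructureError(
                f"HighResDocker: no ligand chain among {self.chains}"
            )
        rng = pose_rng(pose)
        movemap = (
            self.movemap_builder.build(pose)
            if self.movemap_builder is not None
            else MoveMap(rb_chains=set(lig_chains))
        )
        self.n_full_repacks = 0
        self.n_rotamer_trials = 0
        current_energy = score(pose, self.sfx).total
        for cycle in range(1, self.cycles + 1):
            backup = pose.copy()
            for chain in lig_chains:
                direction = rng.standard_normal(3)
                direction /= np.linalg.norm(direction)
                pose.translate_chain(
                    chain, rng.uniform(0.0, HIGH_RES_ANGSTROM) * direction
                )
                axis = rng.standard_normal(3)
                axis /= np.linalg.norm(axis)
                angle = rng.uniform(0.0, np.deg2rad(HIGH_RES_DEGREES))
                pose.rotate_chain_about(
                    chain,
                    Rotation.from_rotvec(angle * axis).as_matrix(),
                    pose.chain_centroid(chain),
                )
            task = self._interface_task(pose, movemap)
            if task.packable_indices():
                if cycle % self.repack_every_nth == 0:
                    seed = int(rng.integers(2**31))
                    packed, _ = pack_anneal(pose, self.sfx, task, seed=seed)
                    pose.assign(packed)
                    self.n_full_repacks += 1
                else:
                    rotamer_trials(pose, self.sfx, task)
                    self.n_rotamer_trials += 1
            new_energy = score(pose, self.sfx).total
            delta = new_energy - current_energy
            if delta < 0 or rng.random() < np.exp(-delta / HIGH_RES_TEMPERATURE):
                current_energy = new_energy
            else:
                pose.assign(backup)
        return Status.SUCCESS


class FinalMinimizer(Mover):
    """Gradient-based rigid-body minimisation of the docked pose."""

    key_name = "FinalMinimizer"

    def __init__(self, sfx=None, movemap_builder=None):
        super().__init__()
        self.sfx = sfx
        self.movemap_builder = movemap_builder

    def parse_my_tag(self, tag, data, filters, movers):
        self.sfx = data.get(
            "scorefxns", tag.get_option("scorefxn", str, "score12"), ScoreFunction
        )
        builder = tag.get_option("movemap_builder", str, None)
        if builder is not None:
            self.movemap_builder = data.get("movemap_builders", builder, MoveMapBuilder)

    def apply(self, pose) -> Status:
        if self.movemap_builder is not None:
            movemap = self.movemap_builder.build(pose)
        else:
            lig = [c for c in pose.chains() if pose.is_ligand_chain(c)]
            movemap = MoveMap(rb_chains=set(lig))
        minimize_pose(pose, self.sfx, movemap)
        return Status.SUCCESS


class InterfaceScoreCalculator(Mover):
    """Record per-term interface scores (bound minus unbound, the unbound
    state built by translating the ligand +500 A along x), the distance the
    ligand travelled from its starting coordinates, its radius of gyration,
    and -- when a native structure is supplied -- the ligand RMSD without
    superposition."""

    key_name = "InterfaceScoreCalculator"

    def __init__(self, chains=(), sfx=None, native: Pose | None = None):
        super().__init__()
        self.chains = list(chains)
        self.sfx = sfx
        self.native = native

    def parse_my_tag(self, tag, data, filters, movers):
        self.chains = tag.get_option_list("chains", str)
        self.sfx = data.get(
            "scorefxns", tag.get_option("scorefxn", str, "score12"), ScoreFunction
        )
        native_path = tag.get_option("native", str, None)
        if native_path is not None:
            from ..structure.pdbio import read_pdb

            self.native = read_pdb(native_path)

    def compute(self, pose) -> dict[str, float]:
        lig_chains = [c for c in self.chains if c in pose.chains()]
        if not lig_chains:
            raise StructureError(
                f"InterfaceScoreCalculator: no ligand chain among {self.chains}"
            )
        bound = score(pose, self.sfx)
        unbound_pose = pose.copy()
        for chain in lig_chains:
            unbound_pose.translate_chain(chain, UNBOUND_SHIFT)
        unbound = score(unbound_pose, self.sfx)
        extras = {
            f"if_{term}": bound.weighted[term] - unbound.weighted[term]
            for term in bound.weighted
        }
        extras["if_total"] = bound.total - unbound.total
        # ligand descriptors (first listed chain)
        chain = lig_chains[0]
        centroid = pose.chain_centroid(chain)
        atoms = np.asarray(
            [
                pos
                for i in pose.chain_indices(chain)
                for _, pos, _, _ in pose.residue(i).sites()
            ]
        )
        extras["ligand_rg"] = float(
            np.sqrt(np.mean(np.sum((atoms - atoms.mean(axis=0)) ** 2, axis=1)))
        )
        if pose.start_coords is not None:
            start_atoms = []
            for i in pose.chain_indices(chain):
                start_atoms.extend(pose.start_coords[i].values())
            start_centroid = np.mean(np.asarray(start_atoms), axis=0)
            extras["ligand_travel"] = float(np.linalg.norm(centroid - start_centroid))
        if self.native is not None:
            native_chain = chain if chain in self.native.chains() else None
            if native_chain is not None:
                native_atoms = np.asarray(
                    [
                        pos
                        for i in self.native.chain_indices(native_chain)
                        for _, pos, _, _ in self.native.residue(i).sites()
                    ]
                )
                if native_atoms.shape == atoms.shape:
                    extras["ligand_rms"] = rmsd_no_superposition(atoms, native_atoms)
        return extras

    def apply(self, pose) -> Status:
        self.extras = self.compute(pose)
        return Status.SUCCESS
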