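"""Metropolis simulated-annealing side-chain packer.

The packer optimises one discrete choice per packable residue (which
rotamer, i.e. which amino-acid type and centroid placement).  The energy
of an assignment decomposes exactly into a fixed background, one-body
terms (rotamer against all fixed sites) and two-body terms (rotamer pairs
on different packable residues), so single-site substitution deltas are
cheap.  Moves are random single-site substitutions accepted by the
Metropolis criterion under a geometric cooling schedule; the best-seen
assignment is recovered at the end and applied to a copy of the pose.

Deterministic for fixed (pose, task, seed, schedule); ties between
equal-energy rotamers resolve to the lowest candidate index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..errors import TaskError
from ..structure import chem
from ..structure.pose import Pose
from ..structure.scorefxn import (
    ScoreFunction,
    pair_energy_to_sites,
    score,
)
from .rotamers import RotamerSet, build_rotamers
from .task import PackerTask

__all__ = ["AnnealSchedule", "pack_anneal", "rotamer_trials", "apply_assignment"]


@dataclass(frozen=True)
class AnnealSchedule:
    t_hi: float = 100.0
    t_lo: float = 0.3
    n_temps: int = 20
    moves_per_temp_factor: int = 10  # moves per temperature = factor * n_sites

    def temperatures(self) -> np.ndarray:
        if self.n_temps == 1:
            return np.array([self.t_lo])
        ratio = (self.t_lo / self.t_hi) ** (1.0 / (self.n_temps - 1))
        return self.t_hi * ratio ** np.arange(self.n_temps)


class _EnergyTables:
    """Exact decomposition of the assignment energy."""

    def __init__(self, pose: Pose, sfx: ScoreFunction, rotset: RotamerSet):
        self.sites = rotset.sites()
        self.rotset = rotset
        packable = set(self.sites)
        # fixed environment: every site except packable centroids
        fpos, frad, fchg = [], [], []
        fres, fchain = [], []
        chain_code = {c: k for k, c in enumerate(pose.chains())}
        for i, res in pose.residues():
            for name, p, r, q in res.sites():
                if i in packable and name == "SCC":
                    continue
                fpos.append(p)
                frad.append(r)
                fchg.append(q)
                fres.append(i)
                fchain.append(chain_code[res.chain_id])
        fpos = np.asarray(fpos)
        frad = np.asarray(frad)
        fchg = np.asarray(fchg)
        fres = np.asarray(fres)
        fchain = np.asarray(fchain)
        self.res_chain = {
            i: chain_code[pose.residue(i).chain_id] for i in self.sites
        }

        # one-body: rotamer vs fixed sites honouring the exclusion rule
        self.e1: dict[int, np.ndarray] = {}
        for i in self.sites:
            ci = self.res_chain[i]
            mask = (np.abs(fres - i) >= 2) | (fchain != ci)
            pos, rad, chg = fpos[mask], frad[mask], fchg[mask]
            energies = np.empty(len(rotset[i]))
            for r, rot in enumerate(rotset[i]):
                aa = chem.AMINO_ACIDS[rot.aa]
                energies[r] = pair_energy_to_sites(
                    rot.position, aa.centroid_radius, aa.charge, pos, rad, chg, sfx
                )
            self.e1[i] = energies

        # two-body: centroid-centroid between packable residues
        self.e2: dict[tuple[int, int], np.ndarray] = {}
        ordered = sorted(self.sites)
        for a_pos, i in enumerate(ordered):
            for j in ordered[a_pos + 1 :]:
                same_chain = self.res_chain[i] == self.res_chain[j]
                if same_chain and abs(i - j) < 2:
                    continue
                table = np.empty((len(rotset[i]), len(rotset[j])))
                for r, rot_i in enumerate(rotset[i]):
                    aa_i = chem.AMINO_ACIDS[rot_i.aa]
                    pos_j = np.asarray([rot.position for rot in rotset[j]])
                    rad_j = np.asarray(
                        [chem.AMINO_ACIDS[rot.aa].centroid_radius for rot in rotset[j]]
                    )
                    chg_j = np.asarray(
                        [chem.AMINO_ACIDS[rot.aa].charge for rot in rotset[j]]
                    )
                    for s in range(len(rotset[j])):
                        table[r, s] = pair_energy_to_sites(
                            rot_i.position,
                            aa_i.centroid_radius,
                            aa_i.charge,
                            pos_j[s : s + 1],
                            rad_j[s : s + 1],
                            chg_j[s : s + 1],
                            sfx,
                        )
                if np.any(table):
                    self.e2[(i, j)] = table

    def assignment_energy(self, assign: dict[int, int]) -> float:
        e = 0.0
        for i in self.sites:
            e += self.e1[i][assign[i]]
        for (i, j), table in self.e2.items():
            e += table[assign[i], assign[j]]
        return float(e)

    def delta(self, assign: dict[int, int], i: int, new_r: int) -> float:
        old_r = assign[i]
        d = self.e1[i][new_r] - self.e1[i][old_r]
        for (a, b), table in self.e2.items():
            if a == i:
                d += table[new_r, assign[b]] - table[old_r, assign[b]]
            elif b == i:
                d += table[assign[a], new_r] - table[assign[a], old_r]
        return float(d)


def apply_assignment(
    pose: Pose, rotset: RotamerSet, assign: dict[int, int]
) -> None:
    """Write an assignment's identities and centroid positions into a pose."""
    for i, r in assign.items():
        rot = rotset[i][r]
        pose.set_residue_identity(i, rot.aa)
        pose.residue(i).centroid = rot.position.copy()


def pack_anneal(
    pose: Pose,
    sfx: ScoreFunction,
    task: PackerTask,
    seed: int,
    schedule: AnnealSchedule | None = None,
) -> tuple[Pose, float]:
    """Run the annealer; returns (new pose with the best-seen assignment
    applied, its total energy under ``sfx``).  The input pose is unmodified.
    """
    schedule = schedule or AnnealSchedule()
    task.finalize()
    rotset = build_rotamers(pose, task)
    if not rotset.sites():
        raise TaskError("no packable residues with rotamer candidates")
    tables = _EnergyTables(pose, sfx, rotset)
    sites = sorted(rotset.sites())
    rng = np.random.default_rng(seed)
    assign = {i: int(rng.integers(len(rotset[i]))) for i in sites}
    energy = tables.assignment_energy(assign)
    best = dict(assign)
    best_energy = energy
    for T in schedule.temperatures():
        for _ in range(schedule.moves_per_temp_factor * len(sites)):
            i = sites[int(rng.integers(len(sites)))]
            new_r = int(rng.integers(len(rotset[i])))
            if new_r == assign[i]:
                continue
            d = tables.delta(assign, i, new_r)
            if d < 0 or rng.random() < np.exp(-d / T):
                assign[i] = new_r
                energy += d
                if energy < best_energy - 1e-12:
                    best = dict(assign)
                    best_energy = energy
    # prefer the lowest candidate index among exactly-tied best rotamers
    for i in sites:
        r = best[i]
        for cand in range(r):
            trial = dict(best)
            trial[i] = cand
            if tables.assignment_energy(trial) <= best_energy + 1e-12:
                best = trial
                break
    out = pose.copy()
    apply_assignment(out, rotset, best)
    return out, score(out, sfx).total


def rotamer_trials(
    pose: Pose, sfx: ScoreFunction, task: PackerTask
) -> Pose:
    """Single greedy pass: per packable residue (ascending pose index),
    place the argmin-energy rotamer given all other residues' current
    coordinates.  Mutates and returns the pose."""
    task.finalize()
    rotset = build_rotamers(pose, task, include_current=True)
    for i in sorted(rotset.sites()):
        res = pose.residue(i)
        # environment: all sites except residue i's own centroid
        pos, rad, chg = [], [], []
        for j, other in pose.residues():
            same_chain = other.chain_id == res.chain_id
            if same_chain and abs(i - j) < 2:
                continue
            for name, p, r, q in other.sites():
                pos.append(p)
                rad.append(r)
                chg.append(q)
        pos = np.asarray(pos) if pos else np.zeros((0, 3))
        rad = np.asarray(rad)
        chg = np.asarray(chg)
        energies = []
        for rot in rotset[i]:
            aa = chem.AMINO_ACIDS[rot.aa]
            energies.append(
                pair_energy_to_sites(
                    rot.position, aa.centroid_radius, aa.charge, pos, rad, chg, sfx
                )
            )
        best = int(np.argmin(np.asarray(energies)))
        rot = rotset[i][best]
        pose.set_residue_identity(i, rot.aa)
        res.centroid = rot.position.copy()
    return pose
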