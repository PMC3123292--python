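"""Surrogate score functions over the reduced residue representation.

A score function is a weighted sum of three pairwise terms evaluated over
all interaction sites (backbone atoms + side-chain centroids, or ligand
atoms) of residue pairs separated by at least two positions in the chain or
belonging to different chains:

* ``rep``  -- soft-sphere repulsion: k * (r_i + r_j - d)^2 for d < r_i + r_j,
  with k scaled by the profile's softness parameter;
* ``atr``  -- a linear attractive well of unit depth reaching from contact
  (d = r_i + r_j) out to contact + 1.5 A;
* ``elec`` -- shifted Coulomb q_i q_j (1/max(d, 1 A) - 1/20 A), zero beyond
  a 20 A cutoff (so all terms are strictly finite-ranged and separated
  partners are exactly non-interacting).

The named weight profiles (score12, soft_rep, ligand, dna, ...) are
surrogate weight sets shipped as small text files so that published
protocol scripts referring to them run unmodified; they do not reproduce
any physical force field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from ..datamap import DataMap
from ..errors import OptionError, StructureError, ValidationError
from ..tagparse import Tag
from .pose import Pose

__all__ = [
    "ScoreFunction",
    "EnergyReport",
    "score",
    "available_profiles",
    "from_profile",
    "parse_scorefxns_block",
    "seed_default_scorefxns",
    "raw_terms_between",
]

TERMS = ("rep", "atr", "elec")

#: accepted Reweight scoretype spellings -> internal term
SCORETYPE_ALIASES = {
    "rep": "rep",
    "fa_rep": "rep",
    "atr": "atr",
    "fa_atr": "atr",
    "elec": "elec",
    "hack_elec": "elec",
    "fa_elec": "elec",
    "coulomb": "elec",
}

#: scoretypes accepted but always contributing a raw value of zero here
INERT_SCORETYPES = ("atom_pair_constraint",)

ATR_WIDTH = 1.5  # Angstrom, width of the attractive well past contact
ATR_DEPTH = 1.0  # well depth per site pair
ELEC_MIN_D = 1.0  # Angstrom, distance floor for the Coulomb term
ELEC_CUTOFF = 20.0  # Angstrom, shifted-truncation cutoff
K_REP = 1.0  # base repulsive spring constant

PROFILE_FILES = {
    "score12": "score12.wts",
    "score12_w_corrections": "score12_w_corrections.wts",
    "soft_rep": "soft_rep.wts",
    "score_docking": "score_docking.wts",
    "ligand": "ligand.wts",
    "ligand_soft_rep": "ligand_soft_rep.wts",
    "enzdes.wts": "enzdes.wts",
    "dna": "dna.wts",
}


@dataclass
class ScoreFunction:
    """Named weight set plus a softness multiplier for the repulsive term."""

    name: str
    weights: dict[str, float] = field(
        default_factory=lambda: {t: 1.0 for t in TERMS}
    )
    softness: float = 1.0

    def set_weight(self, term: str, weight: float) -> None:
        if term not in TERMS and term not in INERT_SCORETYPES:
            raise OptionError(
                f"unknown score term {term!r}; known: {TERMS + INERT_SCORETYPES}"
            )
        self.weights[term] = float(weight)

    def copy(self) -> "ScoreFunction":
        return ScoreFunction(self.name, dict(self.weights), self.softness)


@dataclass
class EnergyReport:
    raw: dict[str, float]
    weighted: dict[str, float]
    total: float


def available_profiles() -> list[str]:
    return list(PROFILE_FILES)


def from_profile(profile: str) -> ScoreFunction:
    """Load a named surrogate weight profile (``term weight`` lines)."""
    if profile not in PROFILE_FILES:
        raise OptionError(
            f"unknown weights profile {profile!r}; available: {available_profiles()}"
        )
    text = (
        resources.files("protoscript")
        .joinpath("data")
        .joinpath("weights")
        .joinpath(PROFILE_FILES[profile])
        .read_text()
    )
    weights = {t: 0.0 for t in TERMS}
    softness = 1.0
    for line in text.splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        term, value = line.split()
        if term == "softness":
            softness = float(value)
        else:
            weights[term] = float(value)
    return ScoreFunction(profile, weights, softness)


# ---------------------------------------------------------------------------
# pairwise evaluation


def _pair_mask(ridx: np.ndarray, cidx: np.ndarray) -> np.ndarray:
    """Upper-triangle mask of interacting site pairs: residues separated by
    >= 2 positions in pose numbering, or on different chains."""
    sep = np.abs(ridx[:, None] - ridx[None, :])
    diff_chain = cidx[:, None] != cidx[None, :]
    interact = (sep >= 2) | diff_chain
    return np.triu(interact, k=1) if interact.ndim else interact


def _raw_terms(pos, rad, chg, mask):
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    rsum = rad[:, None] + rad[None, :]
    overlap = np.where(mask & (d < rsum), rsum - d, 0.0)
    rep = float(np.sum(overlap**2))  # unsoftened; caller applies k
    well = np.clip(1.0 - (d - rsum) / ATR_WIDTH, 0.0, 1.0)
    atr = -ATR_DEPTH * float(np.sum(np.where(mask, well, 0.0)))
    qq = chg[:, None] * chg[None, :]
    coulomb = np.where(
        d < ELEC_CUTOFF, 1.0 / np.maximum(d, ELEC_MIN_D) - 1.0 / ELEC_CUTOFF, 0.0
    )
    elec = float(np.sum(np.where(mask, qq * coulomb, 0.0)))
    return rep, atr, elec


def score(pose: Pose, sfx: ScoreFunction) -> EnergyReport:
    """Deterministic pairwise energy of a pose under one score function."""
    if len(pose) == 0:
        raise StructureError("cannot score an empty pose")
    pos, rad, chg, ridx, cidx = pose.site_arrays()
    mask = _pair_mask(ridx, cidx)
    rep, atr, elec = _raw_terms(pos, rad, chg, mask)
    raw = {"rep": K_REP * sfx.softness * rep, "atr": atr, "elec": elec}
    for term in sfx.weights:
        raw.setdefault(term, 0.0)  # inert terms report zero
    weighted = {t: sfx.weights.get(t, 0.0) * raw[t] for t in raw}
    return EnergyReport(raw=raw, weighted=weighted, total=sum(weighted.values()))


def raw_terms_between(
    pose: Pose, indices_a: list[int], indices_b: list[int], softness: float = 1.0
) -> dict[str, float]:
    """Raw rep/atr/elec restricted to site pairs crossing two residue groups
    (the usual sequence-separation exclusion still applies)."""
    pos, rad, chg, ridx, cidx = pose.site_arrays()
    in_a = np.isin(ridx, list(indices_a))
    in_b = np.isin(ridx, list(indices_b))
    cross = (in_a[:, None] & in_b[None, :]) | (in_b[:, None] & in_a[None, :])
    mask = _pair_mask(ridx, cidx) & cross
    rep, atr, elec = _raw_terms(pos, rad, chg, mask)
    return {"rep": K_REP * softness * rep, "atr": atr, "elec": elec}


def pair_energy_to_sites(
    point: np.ndarray,
    radius: float,
    charge: float,
    pos: np.ndarray,
    rad: np.ndarray,
    chg: np.ndarray,
    sfx: ScoreFunction,
) -> float:
    """Weighted interaction of one site against an array of sites (used by
    the packer's energy tables)."""
    if len(pos) == 0:
        return 0.0
    d = np.linalg.norm(pos - point, axis=1)
    rsum = rad + radius
    overlap = np.where(d < rsum, rsum - d, 0.0)
    rep = K_REP * sfx.softness * float(np.sum(overlap**2))
    well = np.clip(1.0 - (d - rsum) / ATR_WIDTH, 0.0, 1.0)
    atr = -ATR_DEPTH * float(np.sum(well))
    coulomb = np.where(
        d < ELEC_CUTOFF, 1.0 / np.maximum(d, ELEC_MIN_D) - 1.0 / ELEC_CUTOFF, 0.0
    )
    elec = float(np.sum(charge * chg * coulomb))
    w = sfx.weights
    return w.get("rep", 0.0) * rep + w.get("atr", 0.0) * atr + w.get("elec", 0.0) * elec


# ---------------------------------------------------------------------------
# script-section parsing


def parse_scorefxns_block(section: Tag | None, data: DataMap) -> None:
    """Instantiate the SCOREFXNS section into the DataMap.

    The *tag name* of each subtag is the instance name (score functions do
    not take a ``name`` option).  The ``weights`` option selects a surrogate
    profile; each ``Reweight`` subtag overrides one term weight.  Built-in
    profiles are afterwards seeded under their own names wherever the script
    did not declare an instance of that name.
    """
    if section is not None:
        if section.name != "SCOREFXNS":
            raise ValidationError(f"expected <SCOREFXNS>, got <{section.name}>")
        for sub in section.subtags:
            profile = sub.get_option("weights", str, "score12")
            sfx = from_profile(profile)
            sfx.name = sub.name
            for rew in sub.get_tags("Reweight"):
                scoretype = rew.get_option("scoretype")
                weight = rew.get_option("weight", float)
                if scoretype in SCORETYPE_ALIASES:
                    sfx.set_weight(SCORETYPE_ALIASES[scoretype], weight)
                elif scoretype in INERT_SCORETYPES:
                    sfx.set_weight(scoretype, weight)
                else:
                    known = sorted(SCORETYPE_ALIASES) + list(INERT_SCORETYPES)
                    raise OptionError(
                        f"unknown scoretype {scoretype!r} in Reweight of "
                        f"<{sub.name}>; known: {known}"
                    )
            data.put("scorefxns", sub.name, sfx)
    seed_default_scorefxns(data)


def seed_default_scorefxns(data: DataMap) -> None:
    """Make every built-in profile retrievable by its profile name unless
    the script already declared an instance under that name."""
    for profile in PROFILE_FILES:
        if not data.has("scorefxns", profile):
            data.put_default("scorefxns", profile, from_profile(profile))
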