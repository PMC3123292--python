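"""Synthetic test structures: ideal helices, dimers, protein-ligand complexes.

These fixtures are the package's input generator: deterministic per seed,
with idealised geometry.  The helix uses ideal backbone covalent geometry
and alpha-helical torsions (phi = -57, psi = -47 degrees), built by natural
extension (NeRF) placement.  Side-chain centroids are placed in the
backbone plane along the outward CA direction at the type-specific
CA-centroid distance -- a planar simplification of the true Cbeta
direction, adequate for the reduced energy model.

The ligand complex places a small atom-cluster ligand outside the helix
surface at a self-calibrated distance (0.5 A of clearance beyond contact),
so the ligand starts clash-free but inside the attractive well; the chosen
position is recorded in ``pose.provenance["pocket"]``.
"""

from __future__ import annotations

import numpy as np

from ..errors import StructureError
from . import chem
from .pose import LIGAND, POLAR, PROTEIN, Pose, Residue

__all__ = ["make_fixture", "place_atom"]

# ideal backbone geometry (Angstrom / degrees)
B_N_CA, B_CA_C, B_C_N, B_C_O = 1.458, 1.525, 1.329, 1.231
A_N_CA_C, A_CA_C_N, A_C_N_CA, A_CA_C_O = 111.2, 116.2, 121.7, 120.5
PHI_HELIX, PSI_HELIX, OMEGA = -57.0, -47.0, 180.0


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray, bond: float, angle: float, torsion: float
) -> np.ndarray:
    """Place atom d given three predecessors, a bond length to c, the
    b-c-d angle and the a-b-c-d torsion (degrees)."""
    ang = np.deg2rad(angle)
    tor = np.deg2rad(torsion)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _helix_backbone(n: int) -> list[dict[str, np.ndarray]]:
    res: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(A_N_CA_C)
    C = CA + B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0]) * -1.0
    # orient first C consistently: place via a virtual predecessor
    virt = N + np.array([0.0, -1.0, 0.0])
    C = place_atom(virt, N, CA, B_CA_C, A_N_CA_C, PHI_HELIX)
    res.append({"N": N, "CA": CA, "C": C})
    for _ in range(1, n):
        prev = res[-1]
        Nn = place_atom(prev["N"], prev["CA"], prev["C"], B_C_N, A_CA_C_N, PSI_HELIX)
        CAn = place_atom(prev["CA"], prev["C"], Nn, B_N_CA, A_C_N_CA, OMEGA)
        Cn = place_atom(prev["C"], Nn, CAn, B_CA_C, A_N_CA_C, PHI_HELIX)
        res.append({"N": Nn, "CA": CAn, "C": Cn})
    # carbonyl oxygens: torsion psi + 180 about N-CA-C
    for i, r in enumerate(res):
        r["O"] = place_atom(r["N"], r["CA"], r["C"], B_C_O, A_CA_C_O, PSI_HELIX + 180.0)
    return res


def _centroid_for(backbone: dict[str, np.ndarray], aa: chem.AminoAcid) -> np.ndarray:
    ca = backbone["CA"]
    if aa.ca_centroid_distance == 0.0:
        return ca.copy()
    outward = ca - 0.5 * (backbone["N"] + backbone["C"])
    norm = np.linalg.norm(outward)
    if norm < 1e-9:
        outward = np.array([0.0, 0.0, 1.0])
        norm = 1.0
    return ca + aa.ca_centroid_distance * outward / norm


def _protein_residues(
    sequence: str, chain_id: str, start_pdb: int = 1
) -> list[Residue]:
    backbone = _helix_backbone(len(sequence))
    residues = []
    for i, (letter, bb) in enumerate(zip(sequence, backbone)):
        aa = chem.AMINO_ACIDS.get(letter)
        if aa is None:
            raise StructureError(f"unknown amino-acid letter {letter!r}")
        props = {PROTEIN}
        if aa.polar:
            props.add(POLAR)
        residues.append(
            Residue(
                name3=aa.name3,
                chain_id=chain_id,
                pdb_number=start_pdb + i,
                atoms={k: bb[k].copy() for k in ("N", "CA", "C", "O")},
                centroid=_centroid_for(bb, aa),
                properties=props,
            )
        )
    return residues


def _principal_axis(residues: list[Residue]) -> tuple[np.ndarray, np.ndarray]:
    cas = np.asarray([r.atoms["CA"] for r in residues])
    center = cas.mean(axis=0)
    _, _, Vt = np.linalg.svd(cas - center)
    return Vt[0], center


def _perpendicular(u: np.ndarray) -> np.ndarray:
    basis = np.eye(3)
    w = basis[int(np.argmin(np.abs(u)))]
    v = w - np.dot(w, u) * u
    return v / np.linalg.norm(v)


def make_fixture(
    kind: str,
    n_residues: int = 12,
    seed: int = 0,
    sequence: str | None = None,
    separation: float = 9.0,
    ligand_atoms: int = 3,
) -> Pose:
    """Build a synthetic pose: ``helix``, ``dimer`` or ``ligand_complex``.

    Deterministic for a given seed.  ``sequence`` overrides the default
    poly-alanine; ``separation`` is the dimer axis offset in Angstrom.
    """
    if n_residues < 1:
        raise StructureError("n_residues must be >= 1")
    rng = np.random.default_rng(seed)
    seq = sequence or ("A" * n_residues)
    if len(seq) != n_residues:
        raise StructureError("sequence length must equal n_residues")

    if kind == "helix":
        pose = Pose(
            _protein_residues(seq, "A"), provenance={"kind": "helix", "seed": seed}
        )
    elif kind == "dimer":
        a = _protein_residues(seq, "A")
        b = _protein_residues(seq, "B")
        u, _ = _principal_axis(a)
        v = _perpendicular(u)
        for res in b:
            for name in res.atoms:
                res.atoms[name] = res.atoms[name] + separation * v
            res.centroid = res.centroid + separation * v
        pose = Pose(a + b, provenance={"kind": "dimer", "seed": seed})
    elif kind == "ligand_complex":
        protein = _protein_residues(seq, "A")
        u, center = _principal_axis(protein)
        v = _perpendicular(u)
        # protein sites for the clearance search
        sites = []
        for res in protein:
            for _, pos, rad, _ in res.sites():
                sites.append((pos, rad))
        spos = np.asarray([s[0] for s in sites])
        srad = np.asarray([s[1] for s in sites])
        mid_ca = protein[len(protein) // 2].atoms["CA"]
        jitter = 0.4 * rng.standard_normal((ligand_atoms, 3))
        jitter -= jitter.mean(axis=0)

        def clearance(dist: float) -> float:
            atoms = mid_ca + dist * v + jitter
            d = np.linalg.norm(atoms[:, None, :] - spos[None, :, :], axis=-1)
            return float(np.min(d - (srad[None, :] + chem.LIGAND_ATOM_RADIUS)))

        dist = 12.0
        while dist > 2.0 and clearance(dist - 0.1) > 0.5:
            dist -= 0.1
        pocket = mid_ca + dist * v
        atom_names = [f"C{k+1}" for k in range(ligand_atoms)]
        ligand = Residue(
            name3="LG1",
            chain_id="X",
            pdb_number=1,
            atoms={
                name: pocket + jitter[k] for k, name in enumerate(atom_names)
            },
            properties={LIGAND},
        )
        pose = Pose(
            protein + [ligand],
            provenance={"kind": "ligand_complex", "seed": seed, "pocket": pocket},
        )
    else:
        raise StructureError(
            f"unknown fixture kind {kind!r}; choose helix, dimer or ligand_complex"
        )
    pose.take_snapshot()
    return pose
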