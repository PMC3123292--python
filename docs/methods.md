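# Methods

This note documents the models, algorithms, parameters and design choices of
the engine, and what the synthetic fixtures do and do not establish about
real macromolecular data.

## Scope and intent

The package is an architectural re-creation of a protocol-scripting system
for structure modelling.  The *engine semantics* — parsing, factories, the
DataMap, the commutative task algebra, the annealer, trajectory control,
the job loop — are implemented in full and tested exactly.  The *physics*
is deliberately a surrogate: a reduced residue representation and schematic
pairwise energies.  Nothing here predicts real structures; everything here
is exactly reproducible and oracle-checkable, which is the point.

## The script dialect

Scripts are a single recursive tag tree.  Deviations from XML that the
dialect requires: bare (unquoted) option values; whitespace permitted around
`=`; double-quoted values that may contain whitespace but no quotes or angle
brackets; all text outside `<...>` treated as comments.  Errors (mismatched
or unterminated tags, missing `=`, duplicate option keys, multiple top-level
tags) report 1-based line and column, since scripts are user-authored.
Duplicate option keys are an error rather than a silent override.  The only
required top-level sections are `MOVERS` and `PROTOCOLS`.

Section *instantiation* happens in a fixed dependency order — `SCOREFXNS`,
ligand-docking auxiliary sections, `TASKOPERATIONS`, `FILTERS`, `MOVERS`,
`PROTOCOLS` — regardless of document order, because scripts in the wild
declare filters that reference score functions declared later or not at all
(the built-in profiles are then seeded into the DataMap under their own
names, without overriding instances the script declares).

Tag names reserved for sections are treated as reserved at depth 1 only; a
nested tag may reuse such a name.

## Reduced structure model

A protein residue is four backbone atoms (N, CA, C, O) and one side-chain
centroid sphere; a ligand residue is a set of generic atom spheres.  Per
amino-acid type the centroid radius (1.0–3.0 Å), CA–centroid distance
(0–4 Å), POLAR flag, and a coarse partial charge (±1 for D/E/K/R, +0.25 for
H, 0 otherwise) are fixed by a table in `structure/chem.py`; backbone sites
carry fixed radii and amide-like partial charges.  These numbers are
schematic by construction.

PDB I/O goes through gemmi (with a fixed-column pre-validation pass that
reports malformed ATOM/HETATM records with line numbers).  On reading,
side-chain heavy atoms collapse to their mean; on writing, the centroid is
emitted as the pseudo-atom `SCC`.  Round-trips are stable to PDB coordinate
precision (1e-3 Å).  Only altloc ' '/'A' is kept; HETATM residues become
LIGAND residues.

## Surrogate energies

For interaction sites *i, j* of residues separated by ≥ 2 positions in pose
numbering or on different chains, with d the site distance and
r = r_i + r_j the contact distance:

* repulsion: `rep = k·s·(r − d)²` for d < r, with k = 1 and s the profile's
  softness (1.0, or 0.5 for the `soft`/docking profiles);
* attraction: a linear well of unit depth, `atr = −clip(1 − (d − r)/1.5, 0, 1)`
  per pair (full depth inside contact, zero beyond contact + 1.5 Å);
* electrostatics: shifted Coulomb `elec = q_i q_j (1/max(d, 1 Å) − 1/20 Å)`
  truncated at 20 Å.  The truncation makes every term strictly
  finite-ranged, so partners separated by the standard 500 Å unbound shift
  are exactly non-interacting (a bare 1/r tail would leave a ~4e-3 residual
  in ddG; the cutoff is the package's own choice and is continuous at 20 Å).

A score function is a named weight vector over these terms plus the softness
parameter; the shipped profiles (`score12`, `score12_w_corrections` — an
alias, since the corrected set is undefined at this scale — `soft_rep`,
`score_docking`, `ligand`, `ligand_soft_rep`, `enzdes.wts`, `dna`) differ
only in weights/softness and are documented surrogates that let published-
style scripts run unmodified.  `Reweight` subtags override single terms;
`atom_pair_constraint` is accepted as an inert term (raw value 0) because a
corpus script reweights it.  Energy totals are exactly the weighted term sum
and invariant under global rigid motion to 1e-6.

## Geometry kernels

**SASA** is Shrake–Rupley sphere sampling with a deterministic golden-spiral
point set (default 960 points, probe 1.4 Å; fewer than 32 points is an
error).  Per-residue burial for layer assignment is SASA in context divided
by SASA of the residue in isolation; layers are core (< 0.10), surface
(> 0.40), boundary (otherwise), with design alphabets core = AVILMFWY,
surface = DEGHKNPQRST, boundary = their union.

**RMSD** is CA-based; superposition uses Kabsch with the proper-rotation
correction, and collinear point sets are reported as errors (their rotation
is not unique).  Tests verify agreement with an independent quaternion
(Horn) implementation to 1e-9.

## Packing

A fresh `PackerTask` allows everything; operations only clear flags or
intersect allowed sets, so commutativity is structural, not enforced by
sorting.  Finalisation normalises invariants (not packable ⇒ native only;
an emptied allowed set reverts to native repack-only) uniformly after all
operations, preserving order independence.  `IncludeCurrent` and the
command-line globals (`extra_density`, `include_current`) are monotone
OR-flags.  `AddBehaviorRLT` records a behavior token that no built-in
consumes (a documented no-op kept for protocol compatibility).  The resfile
dialect is `NATRO`/`NATAA`/`ALLAA`/`PIKAA letters`, with optional default
commands before `start`.

Rotamers are k centroid placements per allowed amino acid on a golden-spiral
direction grid around CA at the type's CA–centroid distance (k = 3, 6 with
extra density), plus the current conformation when requested.  The annealer
decomposes the assignment energy exactly into background, one-body and
two-body tables, runs single-site Metropolis substitutions through a
geometric schedule (T_hi = 100, T_lo = 0.3, 20 temperatures, 10·n_sites
moves each), recovers the best-seen assignment, and resolves exact energy
ties toward the lowest candidate index for determinism.  The returned energy
is recomputed by a full score of the materialised pose, so it is directly
comparable to the enumeration oracle used in tests; on every enumerable
instance (≤ ~1000 assignments) a 10-seed panel reaches the exhaustive
minimum exactly, and the annealed energy can never fall below it.

## Docking movers

`Translate`/`Rotate` re-try independent random placements from the starting
pose (uniform direction; magnitude U(0, a) or |N(0, a)|; rotation angle
capped at the requested maximum) until an acceptance rule holds or the cycle
budget is spent, then fail the trajectory.  Clash means positive raw
repulsion between the ligand and everything else.  Rotation acceptance needs
raw repulsion ≤ 10 *and* raw attraction ≤ −0.1 (i.e. real contact); both
thresholds are package defaults, stated here because the protocols they come
from say only "a threshold".  `SlideTogether` advances 0.5 Å per step along
the centroid axis until the first clash, then backs off in 0.25 Å steps
until clash-free — for two 2 Å spheres approaching from 20 Å this lands at
exactly the 4.0 Å contact distance, with a gap below 0.25 Å in general.

`HighResDocker` couples a small rigid perturbation (≤ 0.1 Å, ≤ 2.8°) with
interface repacking — a full anneal every Nth cycle, a greedy single-pass
rotamer-trials sweep otherwise — under Metropolis acceptance at T = 0.6 on
the score total.  The minimiser is steepest descent with central-difference
gradients and backtracking line search over per-chain rigid-body DOFs
(rotation vector about the chain centroid + translation), terminating when
the achievable improvement drops below 1e-6 or after 200 iterations; energy
never increases across accepted steps.  Cα restraints (σ from
`Calpha_restraints`, k = 1/(2σ²) per Cα displacement from minimiser entry)
add a quadratic penalty for backbone-flagged residues.

In the reduced representation there are no backbone or side-chain torsion
DOFs, so MoveMap backbone/side-chain flags select *which residues* repack or
feel restraints while the movable minimisation DOFs are rigid-body only;
`minimize_bb` and `minimize_ligand` are recorded faithfully but move nothing
beyond that.  This is the package's design choice for keeping the engine
semantics intact at desk scale.

`InterfaceScoreCalculator` reports per-term bound-minus-unbound scores with
the unbound state built by a +500 Å x translation (deterministic and beyond
every interaction cutoff), ligand travel from the starting snapshot, radius
of gyration, and ligand RMS against a supplied reference without
superposition.

## Filters

`Ddg` is score(bound) − score(separated), the separated state repacked at
the interface (residues within 12 Å of the partner) with seed = repeat
index, averaged over `repeats`; whether the unbound state should be
repacked at all is a modelling choice — this package repacks it and says so
rather than claiming equivalence with any other convention.  `Sasa` is
buried area SASA(A) + SASA(B) − SASA(AB) over the first-chain-vs-rest
partition.  `Rmsd` compares CA positions to the job's starting snapshot
under superposition.  `CompoundStatement` folds clauses left-to-right with
AND/OR/XOR and optional per-clause negation; the first clause's connective
is ignored.  A filter's confidence gates enforcement: 1 strict, 0
report-only (the value is always computed), intermediate values enforce with
that probability using the trajectory's seeded generator.

## Execution and reproducibility

`ParsedProtocol` applies steps in declared order; a mover failure or gated
filter failure aborts the remaining steps and returns the trajectory to the
job distributor, which reloads the input from disk (jobs are fully
isolated), reseeds, and retries up to `max_retries` (default 10 — the
restart semantics themselves impose no bound, so the bound is configuration).
Seeds: job k (over inputs × nstruct) has base seed `seed + k`; attempt a
uses `base + 1000·a`; every stochastic component draws from the trajectory's
single generator in execution order, which yields byte-identical PDB and
scorefile output for identical configuration and seed.  `GenericMonteCarlo`
counts every sub-mover application (including rejected and failed trials)
toward `trials` and restores the best-seen pose.

## Synthetic fixtures

`make_fixture` builds ideal-geometry poly-alanine helices (φ = −57°,
ψ = −47°, ideal bond lengths/angles, NeRF chain extension; centroids placed
in-plane along the outward CA direction — a planar simplification of the
true Cβ direction), two-chain dimers offset 9 Å perpendicular to the helix
axis, and protein–ligand complexes whose 3-atom ligand cluster is placed
along the outward normal at a self-calibrated distance leaving 0.5 Å of
clearance beyond contact (so docking starts clash-free but inside the
attractive well; the point is recorded in `provenance["pocket"]`).  All
fixtures are deterministic per seed.

What the fixtures do *not* emulate: real side-chain torsional statistics,
backbone flexibility, hydrogens, waters, nucleic-acid geometry, or any
physical energy scale.  Passing tests therefore establishes the engine's
*semantics* (ordering, restarts, commutativity, optimality on enumerable
instances, determinism), not predictive accuracy on real complexes.

## Problem sizes

The test suite and the acceptance script use 5–30-residue fixtures, packer
instances of ≤ ~6.5k enumerable assignments (≤ 1000 for the exactness
panel), 960-point SASA sampling, and single-digit docking cycles; these
sizes were chosen so every oracle comparison is exact and the whole suite
runs in well under a minute on one core.

## Known limitations

* The energy model is not physical; profile names are compatibility aliases.
* No backbone/ligand internal DOFs: loop remodelling, backrub-style moves
  and torsion minimisation are out of scope (their script names parse and
  fail loudly at instantiation, pointing at the plugin API).
* DNA residues are recognised as a property but have no geometry builder.
* Quoted values cannot contain literal quotes; values cannot contain angle
  brackets (both are grammar-level restrictions, reported as errors).
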