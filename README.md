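# protoscript

A self-contained protocol-scripting engine for macromolecular modelling, built
around a toy molecular model so that every architectural component is exactly
testable.  It is aimed at people studying or teaching how protocol-scripting
systems for structure modelling are put together — the scripting language,
the plugin machinery, the commutative side-chain-packing task algebra, and
the trajectory-with-restart execution model — without needing a production
force field or external structure sets.

## What it implements

**Scripting language.** Protocols are XML-like scripts with a declaration
phase (`SCOREFXNS`, `TASKOPERATIONS`, `FILTERS`, `MOVERS`, plus ligand-docking
auxiliary sections) and an ordering phase (`PROTOCOLS`).  The dialect is not
XML — bare option values, whitespace around `=`, and free comment text outside
brackets are all legal — so a dedicated recursive-descent parser builds the
tag tree:

```
Tag    := '<' Name Option* '>' Tag* '</' Name '>'  |  '<' Name Option* '/>'
Option := Name '=' Value
```

**Component architecture.** Movers (modify a structure), Filters (evaluate
one and pass/fail it, with a confidence gate in [0, 1]), and TaskOperations
are instantiated by name through singleton factories holding creator
registries; third-party components register one `Creator` and are then usable
from any script.  A two-level `DataMap` (category → name → shared handle)
carries score functions and task operations between components during
parsing; mutating an object through one handle is visible through all others.

**Packing.** A `PackerTask` starts maximally permissive (every protein
residue designable with all 20 amino acids) and task operations may only
restrict it, which makes any operation set commutative:

&nbsp;&nbsp;&nbsp;&nbsp;*allowed(i) = ⋂ₖ allowedₖ(i)*, independent of order.

The packer is a Metropolis simulated-annealing search over one discrete
rotamer choice per packable residue (accept if ΔE < 0, else with probability
exp(−ΔE/T); geometric cooling T: 100 → 0.3 over 20 temperatures; best-seen
recovery).  On instances small enough to enumerate, the annealed energy
equals the exhaustive minimum.

**Structure and energies.** Residues are reduced to backbone atoms plus one
side-chain centroid sphere; energies are a weighted sum of soft-sphere
repulsion, a finite linear attractive well, and a truncated shifted Coulomb
term, evaluated pairwise over interaction sites.  Named weight profiles
(`score12`, `soft_rep`, `ligand_soft_rep`, …) are documented surrogates so
published-style scripts run unmodified.  SASA uses deterministic
golden-spiral Shrake–Rupley sampling; RMSD uses Kabsch superposition.

**Docking and execution.** Rigid-body ligand movers (`StartFrom`,
`Translate`, `Rotate`, `SlideTogether`, `HighResDocker`, `FinalMinimizer`,
`InterfaceScoreCalculator`), composite control flow (`ParsedProtocol` — itself
a mover — `GenericMonteCarlo`, `LoopOver`), energetic/geometric filters
(`Ddg`, `Sasa`, `Rmsd`, `CompoundStatement`), and a job distributor that
loads a fresh structure per attempt, restarts a trajectory on any filter
failure (up to `max_retries`), and writes numbered PDB models plus an aligned
scorefile.

## Worked example

`examples/pack_and_score.py` repacks/designs a six-residue helix and checks
the annealer against brute force over all 972 rotamer assignments:

```
search space: 972 rotamer assignments
exhaustive minimum energy: -48.929549
annealed energy:           -48.929549
designed sequence: AKLSTA -> AALATA
annealer matched brute force: True
```

The annealer reaches the enumerated global minimum exactly, and the two
designable positions (2 and 4) chose alanine over lysine under the surrogate
energy.  `examples/ligand_docking.py` runs the bundled docking script
end-to-end on a synthetic protein–ligand complex:

```
 description   total_score        if_rep        if_atr       if_elec      if_total     ligand_rg  ligand_travel    ligand_rms
complex_0001      -165.251         8.898       -44.120         0.000       -35.222         0.500          3.357         3.494
complex_0002      -165.446         8.057       -43.345         0.000       -35.288         0.500          3.286         3.416
```

`if_total` is the interface score (bound minus ligand-removed energy;
negative = favourable contact), `ligand_travel` the distance the ligand moved
from its input coordinates, `ligand_rg` its radius of gyration, and
`ligand_rms` its deviation from the supplied reference placement.

The other examples cover script parsing (`parse_protocol.py`), order-
independence of task operations (`commutative_taskops.py`), and run-time
plugin registration (`plugin_mover.py`).  A thin command line mirrors the
classic invocation:

```bash
protoscript -s complex.pdb -parser:protocol dock.xml -nstruct 2 -seed 17 -out:path out/
```

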