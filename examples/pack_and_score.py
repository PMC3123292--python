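"""Side-chain packing with the simulated-annealing packer.

Repacks a short helix and compares the annealer's answer against brute
force over every rotamer assignment -- on instances this small the two must
coincide exactly.
"""

import itertools

from protoscript.packing import build_rotamers, default_task, pack_anneal
from protoscript.packing.annealer import apply_assignment
from protoscript.structure import from_profile, make_fixture, score

pose = make_fixture("helix", 6, seed=3, sequence="AKLSTA")
sfx = from_profile("score12")

task = default_task(pose)
for i in task.residue_indices():
    if i in (2, 4):
        task.restrict_allowed(i, {"A", "K"})  # two identities at two sites
    else:
        task.restrict_to_repacking(i)
task.prevent_repacking(6)
task.finalize()

rotset = build_rotamers(pose, task)
print(f"search space: {rotset.n_assignments()} rotamer assignments")

sites = sorted(rotset.sites())
best = min(
    score(
        (lambda w: (apply_assignment(w, rotset, dict(zip(sites, combo))), w)[1])(
            pose.copy()
        ),
        sfx,
    ).total
    for combo in itertools.product(*(range(len(rotset[i])) for i in sites))
)
print(f"exhaustive minimum energy: {best:.6f}")

packed, energy = pack_anneal(pose, sfx, task, seed=0)
print(f"annealed energy:           {energy:.6f}")
print(f"designed sequence: {pose.sequence()} -> {packed.sequence()}")
print("annealer matched brute force:", abs(energy - best) < 1e-9)
# The annealed energy can never be lower than the enumerated minimum; on
# desk-scale instances the default schedule reliably reaches it exactly.
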