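"""Full rigid-body ligand docking from a protocol script.

Builds a synthetic protein-ligand complex, points the bundled docking
script at its binding pocket, and runs the job distributor: low-resolution
placement (StartFrom, Translate, Rotate, SlideTogether), high-resolution
refinement (HighResDocker, FinalMinimizer), and interface scoring.
"""

import os
import tempfile

from protoscript import RunConfig, corpus, run
from protoscript.structure import make_fixture, write_pdb
from protoscript.tagparse import parse_script, write_tag

with tempfile.TemporaryDirectory() as tmp:
    os.chdir(tmp)
    pose = make_fixture("ligand_complex", 16, seed=5)
    write_pdb(pose, "complex.pdb")
    os.makedirs("inputs")
    write_pdb(pose, "inputs/7cpa_7cpa_native.pdb")  # reference for ligand RMS

    # adapt the bundled script: aim StartFrom at this fixture's pocket
    tag = parse_script(corpus.load("ligand_docking"))
    coords = tag.get_tag("MOVERS").get_tag("StartFrom").get_tag("Coordinates")
    for key, value in zip("xyz", pose.provenance["pocket"]):
        coords.options[key] = f"{value:.3f}"
    open("dock.xml", "w").write(write_tag(tag))

    results = run(
        RunConfig(
            inputs=["complex.pdb"],
            protocol_path="dock.xml",
            nstruct=2,
            seed=17,
            out_dir="out",
        )
    )
    for r in results:
        print(f"{r.job_id}: {r.status} (retries={r.retries}) "
              f"total_score={r.total_score:.2f}")
        for key in ("if_total", "ligand_travel", "ligand_rg"):
            if key in r.mover_extras:
                print(f"    {key} = {r.mover_extras[key]:.3f}")
    print("\nscorefile:")
    print(open("out/score.sc").read())
# if_total is the interface score (bound minus ligand-removed energies,
# negative = favourable); ligand_travel is how far the ligand moved from
# its input coordinates (A); ligand_rg its radius of gyration (A).
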