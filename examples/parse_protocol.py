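"""Parse a bundled protocol script and inspect its tag tree.

Shows the declaration/ordering structure of a script, typed option access,
and that writing the tree back out reproduces it exactly.
"""

from protoscript import corpus
from protoscript.tagparse import parse_script, write_tag

text = corpus.load("ligand_docking")
root = parse_script(text)

print("top-level sections:", [t.name for t in root.subtags])

scorefxns = root.get_tag("SCOREFXNS")
soft = scorefxns.get_tag("ligand_soft_rep")
reweight = soft.get_tag("Reweight")
print(
    f"declared score function {soft.name!r} reweights "
    f"{reweight.get_option('scoretype')} to {reweight.get_option('weight', float)}"
)

movers = root.get_tag("MOVERS")
docker = movers.get_tag("HighResDocker")
print(
    f"HighResDocker runs {docker.get_option('cycles', int)} cycles, "
    f"full repack every {docker.get_option('repack_every_Nth', int)}th"
)

steps = [t.options for t in root.get_tag("PROTOCOLS").get_tags("Add")]
print("execution order:", [list(s.values())[0] for s in steps])

assert parse_script(write_tag(root)) == root
print("round-trip through the canonical writer: structurally identical")
# The three execution steps are the low-resolution placement, the
# high-resolution refinement, and the interface score report -- the
# declaration sections above only define the ingredients they use.
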