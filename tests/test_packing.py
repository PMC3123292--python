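"""Packer tasks, commutative operations, resfiles, layers, rotamers,
and the simulated-annealing packer against an exhaustive oracle."""

import itertools

import numpy as np
import pytest

from protoscript.datamap import DataMap
from protoscript.errors import ResfileError, StructureError, TaskError, ValidationError
from protoscript.packing import (
    AnnealSchedule,
    apply_taskops,
    build_rotamers,
    default_task,
    layer_assign,
    pack_anneal,
    parse_task_operation,
    parse_taskoperations_block,
)
from protoscript.packing.annealer import apply_assignment
from protoscript.packing.resfile import parse_resfile_text
from protoscript.packing.taskops import (
    IncludeCurrent,
    OperateOnCertainResidues,
    PreventRepackingRLT,
    ReadResfile,
    ResidueIndexIs,
    ResidueLacksProperty,
    RestrictToRepacking,
    RestrictToRepackingRLT,
)
from protoscript.structure import make_fixture, from_profile, score
from protoscript.structure.pose import Pose
from protoscript.tagparse import parse_script

TASKOPS_SECTION = """
<TASKOPERATIONS>
  <InitializeFromCommandline name = ifcm/>
  <RestrictToRepacking name = no_mutations/>
  <ReadResfile name = rrf filename = myresfile/>
  <OperateOnCertainResidues name = fix20to24>
    <PreventRepackingRLT/>
    <ResidueIndexIs indices = 20,21,22,23,24/>
  </OperateOnCertainResidues>
  <OperateOnCertainResidues name = keepNonpolars>
    <RestrictToRepackingRLT/>
    <ResidueLacksProperty property = POLAR/>
  </OperateOnCertainResidues>
</TASKOPERATIONS>
"""


class TestDefaultTask:
    def test_all_protein_residues_fully_designable(self):
        pose = make_fixture("helix", 5, seed=0)
        task = default_task(pose)
        assert len(task.designable_indices()) == 5
        assert all(len(task.spec(i).allowed) == 20 for i in task.residue_indices())

    def test_ligand_residue_not_packable(self, ligand_complex):
        task = default_task(ligand_complex)
        lig = ligand_complex.chain_indices("X")[0]
        assert not task.spec(lig).packable

    def test_empty_pose_rejected(self):
        with pytest.raises(StructureError):
            default_task(Pose([]))


class TestTaskOperations:
    def test_restrict_to_repacking_freezes_sequence_space(self, helix30_mixed):
        task = apply_taskops(default_task(helix30_mixed), [RestrictToRepacking()])
        for i in task.residue_indices():
            spec = task.spec(i)
            assert not spec.designable
            assert spec.allowed == {spec.native}

    def test_prevent_repacking_on_indices_20_to_24(self, helix30_mixed):
        op = OperateOnCertainResidues(
            selector=ResidueIndexIs(range(20, 25)), rlt=PreventRepackingRLT()
        )
        task = apply_taskops(default_task(helix30_mixed), [op])
        for i in range(20, 25):
            assert not task.spec(i).packable
        assert task.spec(19).packable and task.spec(25).packable

    def test_nonpolar_residues_restricted_polar_untouched(self, helix30_mixed):
        selector = ResidueLacksProperty()
        selector.property = "POLAR"
        op = OperateOnCertainResidues(selector=selector, rlt=RestrictToRepackingRLT())
        task = apply_taskops(default_task(helix30_mixed), [op])
        for i, res in helix30_mixed.residues():
            if "POLAR" in res.properties:
                assert task.spec(i).designable
            else:
                assert not task.spec(i).designable

    def test_exhaustive_permutations_of_three_ops(self, helix30_mixed, tmp_path):
        resfile = tmp_path / "myresfile"
        resfile.write_text("start\n3 A NATRO\n7 A PIKAA ADE\n")
        ops = {
            "rrf": ReadResfile(str(resfile)),
            "fix20to24": OperateOnCertainResidues(
                selector=ResidueIndexIs(range(20, 25)), rlt=PreventRepackingRLT()
            ),
            "keepNonpolars": OperateOnCertainResidues(
                selector=ResidueLacksProperty(), rlt=RestrictToRepackingRLT()
            ),
        }
        ops["keepNonpolars"].selector.property = "POLAR"
        reference = None
        for order in itertools.permutations(ops):
            task = apply_taskops(default_task(helix30_mixed), [ops[k] for k in order])
            if reference is None:
                reference = task
            else:
                assert task == reference

    def test_monotonicity_allowed_sets_only_shrink(self, helix30_mixed, tmp_path):
        resfile = tmp_path / "rf"
        resfile.write_text("NATAA\nstart\n5 A PIKAA KLM\n")
        rng = np.random.default_rng(7)
        pool = _random_op_pool(rng, helix30_mixed, str(resfile))
        task = default_task(helix30_mixed)
        previous = {i: set(task.spec(i).allowed) for i in task.residue_indices()}
        for op in rng.choice(len(pool), size=6):
            apply_taskops(task, [pool[op]])
            for i in task.residue_indices():
                now = task.spec(i).allowed
                assert now <= previous[i]
                previous[i] = set(now)

    def test_randomized_op_sets_commute(self, helix30_mixed, tmp_path):
        resfile = tmp_path / "rf"
        resfile.write_text("start\n2 A NATAA\n9 A PIKAA FW\n")
        rng = np.random.default_rng(2024)
        pool = _random_op_pool(rng, helix30_mixed, str(resfile))
        for _ in range(250):
            size = int(rng.integers(1, 5))
            chosen = [pool[k] for k in rng.choice(len(pool), size=size, replace=False)]
            forward = apply_taskops(default_task(helix30_mixed), chosen)
            shuffled = list(chosen)
            rng.shuffle(shuffled)
            backward = apply_taskops(default_task(helix30_mixed), shuffled)
            assert forward == backward


def _random_op_pool(rng, pose, resfile_path):
    ops = [
        RestrictToRepacking(),
        ReadResfile(resfile_path),
        IncludeCurrent(),
        OperateOnCertainResidues(
            selector=ResidueIndexIs(rng.integers(1, len(pose) + 1, size=4)),
            rlt=PreventRepackingRLT(),
        ),
        OperateOnCertainResidues(
            selector=ResidueIndexIs(rng.integers(1, len(pose) + 1, size=5)),
            rlt=RestrictToRepackingRLT(),
        ),
    ]
    polar_sel = ResidueLacksProperty()
    polar_sel.property = "POLAR"
    ops.append(
        OperateOnCertainResidues(selector=polar_sel, rlt=RestrictToRepackingRLT())
    )
    return ops


class TestTaskOperationParsing:
    def test_printed_section_parses_into_five_named_ops(self):
        data = DataMap()
        parse_taskoperations_block(parse_script(TASKOPS_SECTION), data)
        assert data.names("task_operations") == [
            "ifcm", "no_mutations", "rrf", "fix20to24", "keepNonpolars",
        ]

    def test_layer_option_enables_three_layers(self):
        op = parse_task_operation(
            parse_script("<LayerDesign name = layer layer = core_boundary_surface/>")
        )
        assert op.layers == {"core", "boundary", "surface"}

    def test_two_selectors_rejected(self):
        tag = parse_script(
            "<OperateOnCertainResidues name = bad>"
            "<PreventRepackingRLT/>"
            "<ResidueIndexIs indices = 1/>"
            "<ResidueHasProperty property = PROTEIN/>"
            "</OperateOnCertainResidues>"
        )
        with pytest.raises(ValidationError, match="exactly one selector"):
            parse_task_operation(tag)


class TestResfile:
    def test_natro_freezes_residue(self, helix8):
        task = default_task(helix8)
        parse_resfile_text("start\n3 A NATRO\n").apply(task)
        assert not task.spec(3).packable

    def test_default_command_applies_to_all(self, helix8):
        task = default_task(helix8)
        parse_resfile_text("NATAA\nstart\n").apply(task)
        assert all(not task.spec(i).designable for i in task.residue_indices())

    def test_pikaa_restricts_allowed_set(self, helix8):
        task = default_task(helix8)
        parse_resfile_text("start\n2 A PIKAA ADE\n").apply(task)
        assert task.spec(2).allowed <= {"A", "D", "E"}

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ("start\n3 A WOBBLE\n", "unknown resfile command"),
            ("start\n99 A NATRO\n", "absent"),
            ("start\n3 A PIKAA XYZ123\n", "not amino acids"),
        ],
    )
    def test_bad_resfiles_rejected(self, helix8, text, fragment):
        if "absent" in fragment:
            task = default_task(helix8)
            with pytest.raises(ResfileError, match=fragment):
                parse_resfile_text(text).apply(task)
        else:
            with pytest.raises(ResfileError, match=fragment):
                parse_resfile_text(text)


class TestLayers:
    def test_single_short_chain_has_no_core(self):
        pose = make_fixture("helix", 6, seed=0)
        layers = layer_assign(pose)
        assert "core" not in layers.values()

    def test_buried_residue_is_core(self):
        # a residue surrounded by a cage of ligand spheres is fully buried
        import numpy as np

        from protoscript.structure.pose import LIGAND, Residue
        from protoscript.structure.sasa import golden_spiral

        center = make_fixture("helix", 1, seed=0).residue(1)
        cage = [
            Residue(
                "LG1", "Y", k + 1, {"C1": center.atoms["CA"] + 6.0 * d},
                properties={LIGAND}, atom_radii={"C1": 3.5},
            )
            for k, d in enumerate(golden_spiral(26))
        ]
        pose = Pose([center] + cage)
        from protoscript.structure.sasa import sasa_fractions

        assert sasa_fractions(pose)[1] < 0.10
        assert layer_assign(pose)[1] == "core"


class TestRotamers:
    def test_repack_only_with_current_has_four_candidates(self, helix8):
        task = default_task(helix8)
        apply_taskops(task, [RestrictToRepacking()]).finalize()
        rotset = build_rotamers(helix8, task, include_current=True)
        assert all(len(rotset[i]) == 4 for i in rotset.sites())

    def test_designable_two_types_gives_two_k_candidates(self, helix8):
        task = default_task(helix8)
        for i in task.residue_indices():
            task.restrict_allowed(i, {"A", "G"})
        task.finalize()
        rotset = build_rotamers(helix8, task, include_current=False)
        assert all(len(rotset[i]) == 6 for i in rotset.sites())

    def test_extra_density_doubles_grid(self, helix8):
        task = default_task(helix8)
        apply_taskops(task, [RestrictToRepacking()]).finalize()
        rotset = build_rotamers(helix8, task, include_current=False, extra_density=True)
        assert all(len(rotset[i]) == 6 for i in rotset.sites())

    def test_unpackable_residue_absent(self, helix8):
        task = default_task(helix8)
        task.prevent_repacking(3)
        task.finalize()
        rotset = build_rotamers(helix8, task)
        assert 3 not in rotset.sites()

    def test_candidates_respect_allowed_sets(self, helix8):
        task = default_task(helix8)
        for i in task.residue_indices():
            task.restrict_allowed(i, {"F", "W"})
        task.finalize()
        rotset = build_rotamers(helix8, task)
        for i in rotset.sites():
            assert {r.aa for r in rotset[i]} <= {"F", "W"}


def exhaustive_minimum(pose, sfx, task):
    """Oracle: enumerate every assignment, materialise it and score the
    full pose (independent of the annealer's energy tables)."""
    task.finalize()
    rotset = build_rotamers(pose, task)
    sites = sorted(rotset.sites())
    best = None
    for combo in itertools.product(*(range(len(rotset[i])) for i in sites)):
        work = pose.copy()
        apply_assignment(work, rotset, dict(zip(sites, combo)))
        energy = score(work, sfx).total
        if best is None or energy < best:
            best = energy
    return best


class TestAnnealer:
    def test_single_free_residue_matches_brute_force(self, helix8):
        sfx = from_profile("score12")
        task = default_task(helix8)
        apply_taskops(task, [RestrictToRepacking()])
        for i in task.residue_indices():
            if i != 4:
                task.prevent_repacking(i)
        oracle = exhaustive_minimum(helix8, sfx, task)
        _, energy = pack_anneal(helix8, sfx, task, seed=0)
        assert energy == pytest.approx(oracle, abs=1e-9)

    def test_two_sites_with_design_match_enumeration(self):
        pose = make_fixture("helix", 5, seed=0)
        sfx = from_profile("score12")
        task = default_task(pose)
        for i in task.residue_indices():
            if i in (2, 4):
                task.restrict_allowed(i, {"A", "K"})  # 2 aa x 3 = 6 rotamers
            else:
                task.prevent_repacking(i)
        oracle = exhaustive_minimum(pose, sfx, task)
        for seed in range(10):
            _, energy = pack_anneal(pose, sfx, task, seed=seed)
            assert energy == pytest.approx(oracle, abs=1e-9)

    def test_annealed_energy_never_beats_exhaustive(self, helix8):
        sfx = from_profile("soft_rep")
        task = default_task(helix8)
        for i in task.residue_indices():
            if i <= 3:
                task.restrict_allowed(i, {"A", "S"})
            else:
                task.prevent_repacking(i)
        oracle = exhaustive_minimum(helix8, sfx, task)
        for seed in (0, 1, 2):
            _, energy = pack_anneal(helix8, sfx, task, seed=seed)
            assert energy >= oracle - 1e-9

    def test_deterministic_per_seed(self, helix8):
        sfx = from_profile("score12")
        task = default_task(helix8)
        a, ea = pack_anneal(helix8, sfx, task, seed=9)
        b, eb = pack_anneal(helix8, sfx, task, seed=9)
        assert ea == eb
        assert np.array_equal(a.all_coords(), b.all_coords())
        assert a.sequence() == b.sequence()

    def test_input_pose_unmodified(self, helix8):
        before = helix8.all_coords().copy()
        task = default_task(helix8)
        pack_anneal(helix8, from_profile("score12"), task, seed=1)
        assert np.array_equal(before, helix8.all_coords())

    def test_zero_packable_residues_rejected(self, helix8):
        task = default_task(helix8)
        for i in task.residue_indices():
            task.prevent_repacking(i)
        with pytest.raises(TaskError):
            pack_anneal(helix8, from_profile("score12"), task, seed=0)

    def test_schedule_temperatures_are_geometric(self):
        temps = AnnealSchedule().temperatures()
        assert len(temps) == 20
        assert temps[0] == pytest.approx(100.0)
        assert temps[-1] == pytest.approx(0.3)
        ratios = temps[1:] / temps[:-1]
        assert np.allclose(ratios, ratios[0])
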