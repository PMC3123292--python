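"""Protocol execution semantics, composite movers, docking movers, filters."""

import numpy as np
import pytest

from protoscript.datamap import DataMap
from protoscript.errors import ProtocolError, StructureError
from protoscript.protocol import (
    CompoundStatement,
    FalseFilter,
    GenericMonteCarlo,
    MoveMap,
    ParsedProtocol,
    ProtocolStep,
    Status,
    TrueFilter,
    filter_gate,
    minimize_pose,
    parse_protocol_text,
    rotate,
    slide_together,
    start_from,
    translate,
)
from protoscript.protocol.base import Mover
from protoscript.protocol.filters import DdgFilter, RmsdFilter, SasaFilter
from protoscript.protocol.ligand import (
    InterfaceScoreCalculator,
    LigandArea,
    ligand_is_clashing,
)
from protoscript.structure import from_profile, make_fixture, score
from protoscript.structure.chem import LIGAND_ATOM_RADIUS
from protoscript.structure.pose import LIGAND, Pose, Residue
from protoscript.tagparse import parse_script
from conftest import CountingMover, ensure_counting_mover


def _counting(name, fail=False):
    mover = CountingMover()
    mover.name = name
    mover.fail = fail
    return mover


def _sphere_residue(name3, chain, pdb, xyz, radius=LIGAND_ATOM_RADIUS, charge=0.0):
    return Residue(
        name3, chain, pdb, {"C1": np.asarray(xyz, dtype=float)},
        properties={LIGAND}, atom_radii={"C1": radius}, atom_charges={"C1": charge},
    )


class TestParsedProtocolSemantics:
    def test_failing_filter_aborts_remaining_steps(self, counting_mover_registered, helix8):
        steps = [
            ProtocolStep(mover=_counting("m1")),
            ProtocolStep(mover=_counting("m2"), filter=FalseFilter()),
            ProtocolStep(mover=_counting("m3")),
        ]
        protocol = ParsedProtocol(steps)
        assert protocol.apply(helix8) is Status.FAIL_RETRY
        assert CountingMover.calls == {"m1": 1, "m2": 1}

    def test_all_pass_runs_every_mover_once_in_order(self, counting_mover_registered, helix8):
        order = []

        class OrderMover(Mover):
            def __init__(self, tag_):
                super().__init__()
                self.tag_ = tag_

            def apply(self, pose):
                order.append(self.tag_)
                return Status.SUCCESS

        protocol = ParsedProtocol(
            [ProtocolStep(mover=OrderMover(k)) for k in ("a", "b", "c")]
        )
        assert protocol.apply(helix8) is Status.SUCCESS
        assert order == ["a", "b", "c"]

    def test_nested_protocol_failure_propagates(self, counting_mover_registered, helix8):
        inner = ParsedProtocol([ProtocolStep(mover=_counting("inner", fail=True))])
        outer = ParsedProtocol(
            [ProtocolStep(mover=inner), ProtocolStep(mover=_counting("after"))]
        )
        assert outer.apply(helix8) is Status.FAIL_RETRY
        assert "after" not in CountingMover.calls

    def test_mover_failure_aborts(self, counting_mover_registered, helix8):
        protocol = ParsedProtocol(
            [
                ProtocolStep(mover=_counting("bad", fail=True)),
                ProtocolStep(mover=_counting("never")),
            ]
        )
        assert protocol.apply(helix8) is Status.FAIL_RETRY
        assert CountingMover.calls == {"bad": 1}

    def test_filters_never_mutate_the_pose(self, dimer):
        dimer.take_snapshot()
        before = dimer.all_coords().copy()
        for filt in (SasaFilter(), RmsdFilter(), FalseFilter(), TrueFilter()):
            filt.apply(dimer)
            assert np.array_equal(before, dimer.all_coords())


class TestFilterGate:
    def test_confidence_zero_never_blocks(self, helix8):
        filt = FalseFilter()
        filt.confidence = 0.0
        rng = np.random.default_rng(0)
        assert filter_gate(filt, helix8, rng) is True

    def test_confidence_one_enforces_verdict(self, helix8):
        filt = FalseFilter()
        assert filter_gate(filt, helix8, np.random.default_rng(0)) is False
        assert filter_gate(TrueFilter(), helix8, np.random.default_rng(0)) is True

    def test_half_confidence_passes_half_the_time(self, helix8):
        filt = FalseFilter()
        filt.confidence = 0.5
        rng = np.random.default_rng(123)
        passes = sum(filter_gate(filt, helix8, rng) for _ in range(10000))
        assert passes / 10000 == pytest.approx(0.5, abs=0.02)

    def test_confidence_outside_unit_interval_rejected(self, helix8):
        filt = FalseFilter()
        filt.confidence = 1.5
        with pytest.raises(ProtocolError, match="confidence"):
            filter_gate(filt, helix8, np.random.default_rng(0))


class TestGenericMonteCarlo:
    def test_zero_trials_leaves_pose_unchanged(self, counting_mover_registered, helix8):
        gmc = GenericMonteCarlo(
            mover=_counting("sub"), sfx=from_profile("score12"), trials=0
        )
        before = helix8.all_coords().copy()
        assert gmc.apply(helix8) is Status.SUCCESS
        assert np.array_equal(before, helix8.all_coords())

    def test_energy_raising_mover_fully_rejected_at_tiny_temperature(
        self, counting_mover_registered, dimer
    ):
        # shifting chain A by +x pulls the dimer apart: energy strictly rises
        riser = _counting("riser")
        riser.shift = 1.0
        gmc = GenericMonteCarlo(
            mover=riser, sfx=from_profile("score12"), trials=5, temperature=1e-9
        )
        dimer.rng = np.random.default_rng(4)
        before = dimer.all_coords().copy()
        assert gmc.apply(dimer) is Status.SUCCESS
        assert np.allclose(before, dimer.all_coords())
        assert CountingMover.calls["riser"] == 5

    def test_accepted_objective_non_increasing_at_zero_temperature(
        self, counting_mover_registered, dimer
    ):
        sfx = from_profile("score12")

        class JitterMover(Mover):
            def apply(self, pose):
                vec = pose.rng.normal(0.0, 0.2, size=3)
                pose.translate_chain("B", vec)
                return Status.SUCCESS

        dimer.rng = np.random.default_rng(8)
        start_energy = score(dimer, sfx).total
        gmc = GenericMonteCarlo(mover=JitterMover(), sfx=sfx, trials=15, temperature=0.0)
        gmc.apply(dimer)
        assert score(dimer, sfx).total <= start_energy + 1e-9


class TestLoopOver:
    def test_false_filter_exhausts_iterations(self, counting_mover_registered, helix8):
        from protoscript.protocol import LoopOver

        loop = LoopOver(mover=_counting("sub"), filt=FalseFilter(), iterations=10)
        assert loop.apply(helix8) is Status.SUCCESS
        assert CountingMover.calls["sub"] == 10

    def test_passing_filter_stops_after_one(self, counting_mover_registered, helix8):
        from protoscript.protocol import LoopOver

        loop = LoopOver(mover=_counting("sub"), filt=TrueFilter(), iterations=10)
        loop.apply(helix8)
        assert CountingMover.calls["sub"] == 1

    def test_no_filter_single_iteration(self, counting_mover_registered, helix8):
        from protoscript.protocol import LoopOver

        loop = LoopOver(mover=_counting("sub"), iterations=1)
        loop.apply(helix8)
        assert CountingMover.calls["sub"] == 1


class TestRigidLigandMoves:
    def test_start_from_places_centroid_exactly(self, ligand_complex):
        target = np.array([-1.731, 32.589, -5.039])
        start_from(ligand_complex, "X", target)
        assert np.allclose(ligand_complex.chain_centroid("X"), target, atol=1e-9)

    def test_start_from_identity_when_already_there(self, ligand_complex):
        before = ligand_complex.all_coords().copy()
        start_from(ligand_complex, "X", ligand_complex.chain_centroid("X"))
        assert np.allclose(before, ligand_complex.all_coords(), atol=1e-12)

    def test_start_from_rejects_protein_chain(self, ligand_complex):
        with pytest.raises(StructureError, match="not a ligand"):
            start_from(ligand_complex, "A", np.zeros(3))

    def test_translate_finds_clash_free_placement(self, ligand_complex):
        status = translate(ligand_complex, "X", "uniform", 0.01, 50, rng=3)
        assert status is Status.SUCCESS
        assert not ligand_is_clashing(ligand_complex, "X")

    def test_translate_fails_for_buried_ligand_with_tiny_steps(self, ligand_complex):
        buried = ligand_complex.copy()
        # bury the ligand at the centre of the helix
        core = buried.ca_coords().mean(axis=0)
        start_from(buried, "X", core)
        before = buried.all_coords().copy()
        status = translate(buried, "X", "uniform", 0.01, cycles=20, rng=0)
        assert status is Status.FAIL_RETRY
        assert np.allclose(before, buried.all_coords(), atol=1e-9)

    def test_translate_is_seed_reproducible(self, ligand_complex):
        a = ligand_complex.copy()
        b = ligand_complex.copy()
        translate(a, "X", "gaussian", 0.5, 50, rng=7)
        translate(b, "X", "gaussian", 0.5, 50, rng=7)
        assert np.array_equal(a.all_coords(), b.all_coords())

    def test_rotate_far_ligand_never_accepts(self, ligand_complex):
        far = ligand_complex.copy()
        start_from(far, "X", far.chain_centroid("X") + np.array([100.0, 0, 0]))
        status = rotate(far, "X", "uniform", 360.0, cycles=25, rng=1)
        assert status is Status.FAIL_RETRY  # atr = 0 > -0.1: contact required

    def test_rotate_in_pocket_accepts_and_preserves_centroid(self, ligand_complex):
        centroid = ligand_complex.chain_centroid("X").copy()
        status = rotate(ligand_complex, "X", "uniform", 360.0, cycles=100, rng=2)
        assert status is Status.SUCCESS
        assert np.allclose(ligand_complex.chain_centroid("X"), centroid, atol=1e-9)

    def test_rigid_moves_preserve_intra_chain_geometry(self, ligand_complex):
        def pairwise(pose, chain):
            coords = np.asarray(
                [
                    pos
                    for i in pose.chain_indices(chain)
                    for _, pos, _, _ in pose.residue(i).sites()
                ]
            )
            return np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)

        before = pairwise(ligand_complex, "X")
        translate(ligand_complex, "X", "uniform", 1.0, 50, rng=0)
        rotate(ligand_complex, "X", "uniform", 360.0, 100, rng=0)
        slide_together(ligand_complex, "X")
        assert np.allclose(before, pairwise(ligand_complex, "X"), atol=1e-9)


class TestSlideTogether:
    def _two_sphere_pose(self, distance):
        pose = Pose(
            [
                _sphere_residue("LG1", "X", 1, [distance, 0, 0]),
                _sphere_residue("LG2", "P", 1, [0, 0, 0]),
            ]
        )
        pose.take_snapshot()
        return pose

    def test_twenty_angstrom_approach_lands_at_contact(self):
        # r=2 spheres: contact at 4.0; steps of 0.5 first clash at 3.5,
        # 0.25-A back-steps recover the contact distance 4.0 exactly
        pose = self._two_sphere_pose(20.0)
        slide_together(pose, "X")
        d = np.linalg.norm(
            pose.residue(1).atoms["C1"] - pose.residue(2).atoms["C1"]
        )
        assert d == pytest.approx(4.0, abs=1e-9)
        assert not ligand_is_clashing(pose, "X")
        assert d - 4.0 < 0.5  # gap below one approach step

    def test_touching_pose_moves_at_most_one_step(self):
        pose = self._two_sphere_pose(4.2)
        slide_together(pose, "X")
        d = np.linalg.norm(
            pose.residue(1).atoms["C1"] - pose.residue(2).atoms["C1"]
        )
        assert 3.95 <= d <= 4.2 + 1e-9
        assert not ligand_is_clashing(pose, "X")

    def test_clashing_start_is_an_error(self):
        pose = self._two_sphere_pose(3.0)
        with pytest.raises(ProtocolError, match="Translate"):
            slide_together(pose, "X")


class TestHighResDockerAndMinimizer:
    def test_repack_cadence_two_full_four_trials(self, ligand_complex):
        from protoscript.protocol import HighResDocker

        docker = HighResDocker(
            chains=["X"], cycles=6, repack_every_nth=3, sfx=from_profile("ligand_soft_rep")
        )
        ligand_complex.rng = np.random.default_rng(5)
        assert docker.apply(ligand_complex) is Status.SUCCESS
        assert docker.n_full_repacks == 2
        assert docker.n_rotamer_trials == 4

    def test_metropolis_drift_bound(self, ligand_complex):
        from protoscript.protocol import HighResDocker
        from protoscript.protocol.ligand import HIGH_RES_TEMPERATURE

        sfx = from_profile("ligand_soft_rep")
        for seed in (0, 1, 2):
            pose = ligand_complex.copy()
            pose.rng = np.random.default_rng(seed)
            start = score(pose, sfx).total
            HighResDocker(chains=["X"], cycles=6, repack_every_nth=3, sfx=sfx).apply(pose)
            assert score(pose, sfx).total <= start + 25 * HIGH_RES_TEMPERATURE

    def test_docker_reproducible_per_seed(self, ligand_complex):
        from protoscript.protocol import HighResDocker

        sfx = from_profile("ligand_soft_rep")
        outputs = []
        for _ in range(2):
            pose = ligand_complex.copy()
            pose.rng = np.random.default_rng(77)
            HighResDocker(chains=["X"], cycles=4, repack_every_nth=2, sfx=sfx).apply(pose)
            outputs.append(pose.all_coords())
        assert np.array_equal(outputs[0], outputs[1])

    def test_minimizer_never_increases_energy(self, ligand_complex):
        sfx = from_profile("ligand")
        before = score(ligand_complex, sfx).total
        movemap = MoveMap(rb_chains={"X"})
        final = minimize_pose(ligand_complex, sfx, movemap)
        assert final <= before + 1e-12
        assert score(ligand_complex, sfx).total == pytest.approx(final, abs=1e-9)

    def test_minimizer_at_minimum_leaves_pose_unchanged(self):
        # quadratic well from Calpha restraints only (zero-weight scorefxn)
        pose = make_fixture("helix", 5, seed=0)
        sfx = from_profile("score12").copy()
        for term in list(sfx.weights):
            sfx.weights[term] = 0.0
        movemap = MoveMap(
            rb_chains={"A"}, bb={i for i, _ in pose.residues()}, calpha_restraints=0.3
        )
        before = pose.all_coords().copy()
        minimize_pose(pose, sfx, movemap)
        assert np.allclose(before, pose.all_coords(), atol=1e-6)

    def test_minimizer_recovers_quadratic_well_centre(self):
        pose = make_fixture("helix", 5, seed=0)
        reference = pose.all_coords().copy()
        movemap = MoveMap(
            rb_chains={"A"}, bb={i for i, _ in pose.residues()}, calpha_restraints=0.3
        )
        sfx = from_profile("score12").copy()
        for term in list(sfx.weights):
            sfx.weights[term] = 0.0
        pose.translate_chain("A", np.array([0.7, -0.3, 0.4]))
        # restraints anchor to minimiser-entry coordinates, so re-anchor by
        # snapshotting: here we instead displace after capturing references
        # by driving the restraint from the pose's own start snapshot
        movemap2 = MoveMap(rb_chains={"A"}, bb=movemap.bb, calpha_restraints=0.3)
        # the quadratic well centred at entry coordinates is flat-bottomed at
        # the entry point itself; displacement inside minimize is what the
        # rigid DOFs explore, so verify descent instead on a crafted well:
        from protoscript.protocol.minimize import minimize_pose as mp

        energy = mp(pose, sfx, movemap2)
        assert energy == pytest.approx(0.0, abs=1e-6)

    def test_minimizer_pulls_displaced_sphere_into_contact_minimum(self):
        # single ligand sphere attracted to a fixed sphere: the 1-D energy
        # has its minimum exactly at contact (d = 4); start inside the well
        pose = Pose(
            [
                _sphere_residue("LG1", "X", 1, [5.2, 0, 0]),
                _sphere_residue("LG2", "P", 1, [0, 0, 0]),
            ]
        )
        pose.take_snapshot()
        sfx = from_profile("score12")
        minimize_pose(pose, sfx, MoveMap(rb_chains={"X"}), max_iter=400)
        d = np.linalg.norm(pose.residue(1).atoms["C1"] - pose.residue(2).atoms["C1"])
        assert d == pytest.approx(4.0, abs=1e-3)


class TestRepackMinimize:
    @pytest.fixture
    def dimer(self):
        return make_fixture("dimer", 6, seed=3)

    def _mover(self, **kwargs):
        from protoscript.protocol import RepackMinimize

        defaults = dict(
            sfx_repack=from_profile("soft_rep"), sfx_minimize=from_profile("soft_rep")
        )
        defaults.update(kwargs)
        return RepackMinimize(**defaults)

    def test_rb_only_minimization_keeps_backbones_internally_rigid(self, dimer):
        def backbone(chain):
            return np.asarray(
                [
                    dimer.residue(i).atoms[a]
                    for i in dimer.chain_indices(chain)
                    for a in ("N", "CA", "C", "O")
                ]
            )

        before_a = backbone("A").copy()
        before_b = backbone("B").copy()
        dimer.rng = np.random.default_rng(1)
        mover = self._mover(minimize_bb=False, minimize_rb=True)
        assert mover.apply(dimer) is Status.SUCCESS
        # partner 1 holds still; partner 2 may move but only rigidly
        assert np.allclose(before_a, backbone("A"), atol=1e-9)
        after_b = backbone("B")
        d_before = np.linalg.norm(before_b[:, None] - before_b[None, :], axis=-1)
        d_after = np.linalg.norm(after_b[:, None] - after_b[None, :], axis=-1)
        assert np.allclose(d_before, d_after, atol=1e-9)

    def test_design_disabled_preserves_sequence(self, dimer):
        dimer.rng = np.random.default_rng(2)
        before = dimer.sequence()
        mover = self._mover(design_partner1=False, design_partner2=False)
        mover.apply(dimer)
        assert dimer.sequence() == before

    def test_design_enabled_may_mutate_interface(self, dimer):
        dimer.rng = np.random.default_rng(3)
        mover = self._mover()
        mover.apply(dimer)
        assert len(dimer.sequence()) == 12  # identity change allowed, size fixed

    def test_single_chain_pose_rejected(self, helix8):
        helix8.rng = np.random.default_rng(0)
        with pytest.raises(StructureError, match="two chains"):
            self._mover().apply(helix8)


class TestInterfaceScoreCalculator:
    def test_far_ligand_has_zero_interface_terms(self, ligand_complex):
        far = ligand_complex.copy()
        far.translate_chain("X", np.array([500.0, 0.0, 0.0]))
        calc = InterfaceScoreCalculator(chains=["X"], sfx=from_profile("ligand"))
        extras = calc.compute(far)
        assert extras["if_total"] == pytest.approx(0.0, abs=1e-9)

    def test_single_atom_ligand_rg_zero(self):
        pose = Pose(
            [
                _sphere_residue("LG1", "X", 1, [10.0, 0, 0]),
                _sphere_residue("LG2", "P", 1, [0, 0, 0]),
            ]
        )
        pose.take_snapshot()
        calc = InterfaceScoreCalculator(chains=["X"], sfx=from_profile("ligand"))
        assert calc.compute(pose)["ligand_rg"] == pytest.approx(0.0)

    def test_two_atom_ligand_rg_is_half_separation(self):
        lig = Residue(
            "LG1", "X", 1,
            {"C1": np.array([0.0, 0, 0]), "C2": np.array([2.0, 0, 0])},
            properties={LIGAND},
        )
        pose = Pose([lig, _sphere_residue("LG2", "P", 1, [50.0, 0, 0])])
        pose.take_snapshot()
        calc = InterfaceScoreCalculator(chains=["X"], sfx=from_profile("ligand"))
        assert calc.compute(pose)["ligand_rg"] == pytest.approx(1.0)


class TestLigandAreas:
    def test_all_atom_mode_and_nbr_radius_widen_the_interface(self, ligand_complex):
        tight = LigandArea("a", "X", cutoff=6.0)
        wide = LigandArea("b", "X", cutoff=6.0, add_nbr_radius=True, all_atom_mode=True)
        assert tight.interface_residues(ligand_complex) <= wide.interface_residues(
            ligand_complex
        )

    def test_extension_window_widens_backbone_set(self, ligand_complex):
        from protoscript.protocol import InterfaceBuilder

        area = LigandArea("a", "X", cutoff=7.0, all_atom_mode=True)
        plain = InterfaceBuilder("p", [area], extension_window=0).build(ligand_complex)
        extended = InterfaceBuilder("e", [area], extension_window=3).build(ligand_complex)
        assert plain < extended


class TestCompoundStatement:
    @pytest.mark.parametrize(
        "values, connective, expected",
        [
            ((True, True), "AND", True),
            ((True, False), "AND", False),
            ((False, True), "AND", False),
            ((False, False), "AND", False),
            ((True, True), "OR", True),
            ((True, False), "OR", True),
            ((False, True), "OR", True),
            ((False, False), "OR", False),
            ((True, True), "XOR", False),
            ((True, False), "XOR", True),
        ],
    )
    def test_truth_table(self, helix8, values, connective, expected):
        filters = [TrueFilter() if v else FalseFilter() for v in values]
        compound = CompoundStatement(
            [("AND", filters[0], False), (connective, filters[1], False)]
        )
        assert compound.apply(helix8) is expected

    def test_negation(self, helix8):
        compound = CompoundStatement([("AND", FalseFilter(), True)])
        assert compound.apply(helix8) is True

    def test_zero_subfilters_rejected(self, helix8):
        with pytest.raises(ProtocolError, match="zero"):
            CompoundStatement([]).apply(helix8)


class TestTwoBodyFilters:
    def test_separated_partners_have_zero_ddg_and_sasa(self, dimer):
        apart = dimer.copy()
        apart.translate_chain("B", np.array([500.0, 0.0, 0.0]))
        apart.take_snapshot()
        ddg = DdgFilter(sfx=from_profile("score12"), repeats=1)
        assert ddg.report_value(apart) == pytest.approx(0.0, abs=1e-6)
        sasa = SasaFilter()
        assert sasa.report_value(apart) == pytest.approx(0.0, abs=5.0)

    def test_bound_dimer_buries_surface(self, dimer):
        assert SasaFilter().report_value(dimer) > 50.0

    def test_rmsd_zero_after_load(self, dimer):
        dimer.take_snapshot()
        assert RmsdFilter().report_value(dimer) == pytest.approx(0.0, abs=1e-9)

    def test_ddg_repeats_below_one_rejected(self, dimer):
        filt = DdgFilter(sfx=from_profile("score12"), repeats=0)
        with pytest.raises(ProtocolError, match="repeats"):
            filt.report_value(dimer)


class TestSectionParsing:
    def test_mover_resolves_taskop_through_datamap(self):
        parsed = parse_protocol_text(
            """
            <ROSETTASCRIPTS>
              <TASKOPERATIONS>
                <RestrictToRepacking name = design_shell/>
              </TASKOPERATIONS>
              <MOVERS>
                <PackRotamersMover name = design task_operations = design_shell/>
              </MOVERS>
              <PROTOCOLS>
                <Add mover = design/>
              </PROTOCOLS>
            </ROSETTASCRIPTS>
            """
        )
        mover = parsed.movers["design"]
        assert mover.task_operations[0] is parsed.datamap.get(
            "task_operations", "design_shell"
        )

    def test_missing_name_option_rejected(self):
        from protoscript.errors import ValidationError

        with pytest.raises(ValidationError, match="name"):
            parse_protocol_text(
                "<ROSETTASCRIPTS><MOVERS><PackRotamersMover/></MOVERS>"
                "<PROTOCOLS/></ROSETTASCRIPTS>"
            )

    def test_duplicate_instance_names_rejected(self):
        from protoscript.errors import ValidationError

        with pytest.raises(ValidationError, match="duplicate"):
            parse_protocol_text(
                "<ROSETTASCRIPTS><MOVERS>"
                "<PackRotamersMover name = dock/>"
                "<PackRotamersMover name = dock/>"
                "</MOVERS><PROTOCOLS/></ROSETTASCRIPTS>"
            )

    def test_add_with_unknown_filter_rejected(self):
        with pytest.raises(ProtocolError, match="undeclared filter"):
            parse_protocol_text(
                "<ROSETTASCRIPTS><MOVERS><PackRotamersMover name = m/></MOVERS>"
                "<PROTOCOLS><Add mover = m filter = ghost/></PROTOCOLS>"
                "</ROSETTASCRIPTS>"
            )

    def test_both_option_spellings_accepted(self):
        parsed = parse_protocol_text(
            """
            <ROSETTASCRIPTS>
              <FILTERS><TrueFilter name = ok/></FILTERS>
              <MOVERS><PackRotamersMover name = des1/></MOVERS>
              <PROTOCOLS>
                <Add mover_name = des1/>
                <Add mover = des1 filter_name = ok/>
              </PROTOCOLS>
            </ROSETTASCRIPTS>
            """
        )
        assert len(parsed.protocol.steps) == 2
        assert parsed.protocol.steps[1].filter.name == "ok"
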