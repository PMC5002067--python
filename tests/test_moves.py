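"""Move generators: rigidity, invertibility, and the fused-segment contract."""

import numpy as np
import pytest

import naturalmoves as nm
from naturalmoves.moves import (
    StepConfig,
    build_moveset,
    propose_bend,
    propose_rigid,
    propose_torsion,
    rigid_transform,
)


def pdist(coords, atoms):
    sub = coords[atoms]
    return np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)


class TestBuildMoveset:
    def test_groove_010_has_three_rigid_generators(self, toy_groove):
        d = toy_groove.decomposition
        eff = nm.apply_test_case(d, nm.parse_testcase_label("010", d))
        ms = build_moveset(eff, toy_groove.conformation)
        kinds = [g.kind for g in ms.generators]
        assert kinds.count("rigid") == 3 and kinds.count("torsion") == 0

    def test_dna_001_per_nucleotide_rigid_no_torsions(self, bdna_marked, ddd_decomposition):
        eff = nm.apply_test_case(
            ddd_decomposition, nm.parse_testcase_label("001", ddd_decomposition)
        )
        ms = build_moveset(eff, bdna_marked)
        kinds = [g.kind for g in ms.generators]
        assert kinds.count("rigid") == 24  # every nucleotide its own segment
        assert kinds.count("torsion") == 0  # hydroxyl torsions frozen

    def test_dna_111_activates_four_mark_torsions(self, bdna_marked, ddd_decomposition):
        eff = nm.apply_test_case(
            ddd_decomposition, nm.parse_testcase_label("111", ddd_decomposition)
        )
        ms = build_moveset(eff, bdna_marked)
        assert [g.kind for g in ms.generators].count("torsion") == 4

    def test_fully_fused_chain_single_generator(self):
        helix = nm.coarse_grain_protein(nm.make_ideal_helix(12))
        from naturalmoves.decomposition import (
            Chain,
            Decomposition,
            MoltenZone,
            Segment,
            StructureIndex,
        )

        d = Decomposition(
            structure=StructureIndex(chains=(Chain("A", tuple(range(1, 13))),)),
            segments=(Segment("S1", "A", 1, 5), Segment("S2", "A", 8, 12)),
            molten_zones=(
                MoltenZone("M", "residue", "A", residues=(6, 7), flanking=("S1", "S2")),
            ),
        )
        eff = nm.apply_test_case(d, nm.parse_testcase_label("0", d))
        ms = build_moveset(eff, helix)
        assert len(ms.generators) == 1
        assert len(ms.generators[0].atoms) == helix.n_atoms


class TestRigidProposal:
    def test_zero_step_limits_identity(self, toy_groove):
        coords = toy_groove.conformation.coords.copy()
        rng = np.random.default_rng(0)
        atoms = np.arange(10)
        propose_rigid(coords, atoms, rng, max_trans=0.0, max_rot=0.0)
        np.testing.assert_array_equal(coords, toy_groove.conformation.coords)

    def test_internal_distances_preserved(self, toy_groove):
        rng = np.random.default_rng(1)
        coords = toy_groove.conformation.coords.copy()
        atoms = np.arange(30)
        before = pdist(coords, atoms)
        for _ in range(20):
            propose_rigid(coords, atoms, rng, max_trans=1.0, max_rot=20.0)
        assert np.abs(pdist(coords, atoms) - before).max() < 1e-9

    def test_atoms_outside_segment_untouched(self, toy_groove):
        rng = np.random.default_rng(2)
        coords = toy_groove.conformation.coords.copy()
        atoms = np.arange(12)
        propose_rigid(coords, atoms, rng, 1.0, 10.0)
        np.testing.assert_array_equal(coords[12:], toy_groove.conformation.coords[12:])

    def test_inverse_restores_coordinates(self, toy_groove):
        rng = np.random.default_rng(3)
        coords = toy_groove.conformation.coords.copy()
        atoms = np.arange(25)
        t, axis, angle, center = propose_rigid(coords, atoms, rng, 1.0, 15.0)
        # undo: subtract translation, rotate back about the shifted centre
        rigid_transform(coords, atoms, -t, axis, 0.0)
        rigid_transform(coords, atoms, np.zeros(3), axis, -angle, center=center)
        assert np.abs(coords - toy_groove.conformation.coords).max() < 1e-9


class TestTorsionProposal:
    def _setup(self, bdna_marked, ddd_decomposition):
        eff = nm.apply_test_case(
            ddd_decomposition, nm.parse_testcase_label("111", ddd_decomposition)
        )
        ms = build_moveset(eff, bdna_marked, StepConfig(max_torsion=90.0))
        gen = next(g for g in ms.generators if g.label == "phi1-A9")
        return gen

    def test_zero_rotation_identity(self, bdna_marked, ddd_decomposition):
        gen = self._setup(bdna_marked, ddd_decomposition)
        coords = bdna_marked.coords.copy()
        rng = np.random.default_rng(0)
        propose_torsion(coords, gen.atoms, gen.axis, rng, max_angle=0.0)
        np.testing.assert_array_equal(coords, bdna_marked.coords)

    def test_forward_backward_identity(self, bdna_marked, ddd_decomposition):
        from naturalmoves.moves import _axis_rotation

        gen = self._setup(bdna_marked, ddd_decomposition)
        coords = bdna_marked.coords.copy()
        _axis_rotation(coords, gen.atoms, gen.axis[0], gen.axis[1], 37.0)
        _axis_rotation(coords, gen.atoms, gen.axis[0], gen.axis[1], -37.0)
        assert np.abs(coords - bdna_marked.coords).max() < 1e-9

    def test_hydroxyl_rotation_moves_only_moving_set(self, bdna_marked, ddd_decomposition):
        from naturalmoves.moves import _axis_rotation

        gen = self._setup(bdna_marked, ddd_decomposition)
        coords = bdna_marked.coords.copy()
        _axis_rotation(coords, gen.atoms, gen.axis[0], gen.axis[1], 90.0)
        changed = np.where(np.any(coords != bdna_marked.coords, axis=1))[0]
        assert set(changed.tolist()) <= set(gen.atoms.tolist())
        # the hydroxyl oxygen genuinely moved; ring atoms are fixed
        o5 = bdna_marked.atom_index("A", 9, "O5")
        assert np.linalg.norm(coords[o5] - bdna_marked.coords[o5]) > 0.1
        # bond lengths preserved
        conf2 = bdna_marked.copy()
        conf2.coords = coords
        assert nm.validate_geometry(conf2, tol=1e-9).ok

    def test_degenerate_axis_rejected(self):
        coords = np.zeros((3, 3))
        with pytest.raises(ValueError, match="degenerate"):
            propose_torsion(
                coords, np.array([2]), (0, 1), np.random.default_rng(0), 10.0
            )


class TestBendProposal:
    def test_bend_preserves_bond_lengths(self):
        coords = np.array([[0.0, 0, 0], [1.5, 0, 0], [3.0, 1.0, 0], [4.0, 2.0, 0.5]])
        before = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        propose_bend(coords, np.array([2, 3]), (0, 1, 2), np.random.default_rng(1), 30.0)
        after = np.linalg.norm(np.diff(coords, axis=0), axis=1)
        np.testing.assert_allclose(after, before, atol=1e-9)


class TestFusedSegmentContract:
    def test_deactivated_zone_preserves_relative_orientation(self, toy_groove):
        """Segments fused by a deactivated molten zone keep their mutual
        arrangement over an entire run (the fused pair shares one rigid
        generator)."""
        d = toy_groove.decomposition
        eff = nm.apply_test_case(d, nm.parse_testcase_label("010", d))
        conf = toy_groove.conformation
        ms = build_moveset(eff, conf, StepConfig(0.5, 5.0))
        model = nm.protein_energy_model(conf)
        cfg = nm.SamplerConfig(temperatures=(300.0,), iterations=2000, seed=4, sample_interval=200)

        fused = next(s for s in eff.effective_segments if s.id == "B2+B3")
        atoms = np.concatenate(
            [conf.residue_atoms("B", r) for r in fused.residues]
        )
        before = pdist(conf.coords, atoms)
        traj, _ = nm.run_mc(conf, ms, model, cfg)
        for i in range(traj.n_frames):
            assert np.abs(pdist(traj.frames[i], atoms) - before).max() < 1e-6
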