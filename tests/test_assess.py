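"""CAPRI-style metrics, tier classification, and difficulty labels."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from tmdock import (
    RigidTransform, Tier, apply_transform, classify_quality, fnat,
    interface_rmsd, ligand_rmsd, native_contacts, superpose,
)
from tmdock.assess import (
    assess_model, classify_difficulty, difficulty_from_delta, report_top_n,
    write_assessment_table,
)
from tmdock.errors import (
    CorrespondenceError, DegenerateReferenceError,
    DegenerateSuperpositionError,
)
from tmdock.ranking import DockingResult, ScoredPose

from conftest import random_structure
from oracles import brute_force_contacts, horn_superpose, truth_table_tier
from test_structio import make_structure


def two_residue_pair(gap: float):
    """Single-residue receptor and ligand with closest atoms ``gap`` apart."""
    rec = make_structure([[0.0, 0.0, 0.0], [0.5, 0.0, 0.0]], resnums=[1, 1],
                         names=["CA", "CB"])
    lig = make_structure([[0.5 + gap, 0.0, 0.0], [1.5 + gap, 0.0, 0.0]],
                         resnums=[1, 1], names=["CA", "CB"], chain="B")
    return rec, lig


class TestNativeContacts:
    def test_contact_inside_cutoff(self):
        assert len(native_contacts(two_residue_pair(4.9))) == 1

    def test_no_contact_outside_cutoff(self):
        assert len(native_contacts(two_residue_pair(5.1))) == 0

    def test_hydrogens_ignored(self):
        rec = make_structure([[0, 0, 0]], elements=["C"])
        lig = make_structure([[3.0, 0, 0]], elements=["H"], chain="B")
        assert len(native_contacts((rec, lig))) == 0

    def test_matches_brute_force_on_toy_complex(self, ridge_dimer):
        rec = ridge_dimer.receptor
        lig = ridge_dimer.bound_ligand()
        # clip to a 5-residue slice each to keep the O(n^2) oracle cheap
        rsub = rec.select(rec.residue_numbers <= 5)
        lsub = lig.select(lig.residue_numbers <= 5)
        assert native_contacts((rsub, lsub)) == brute_force_contacts(rsub, lsub)

    def test_random_structures_match_brute_force(self):
        rec = random_structure(40, seed=1, spread=8.0)
        lig = random_structure(40, seed=2, spread=8.0)
        assert native_contacts((rec, lig)) == brute_force_contacts(rec, lig)


class TestFnat:
    def test_identical_model_is_one(self, ridge_dimer):
        ref = ridge_dimer.reference_complex()
        assert fnat(ref, ref) == pytest.approx(1.0)

    def test_far_translated_ligand_is_zero(self, ridge_dimer):
        rec, lig = ridge_dimer.reference_complex()
        far = lig.with_coords(lig.coords + [50.0, 0.0, 0.0])
        assert fnat((rec, far), (rec, lig)) == 0.0

    def test_half_preserved_contacts(self):
        # two native contacts (residues 1-1 and 2-2); the model moves ligand
        # residue 2 away, preserving exactly one
        rec = make_structure([[0, 0, 0], [0.5, 0, 0],
                              [0, 20, 0], [0.5, 20, 0]],
                             resnums=[1, 1, 2, 2], names=["CA", "CB"] * 2)
        lig_ref = make_structure([[4, 0, 0], [4.5, 0, 0],
                                  [4, 20, 0], [4.5, 20, 0]],
                                 resnums=[1, 1, 2, 2],
                                 names=["CA", "CB"] * 2, chain="B")
        lig_model = lig_ref.with_coords(
            lig_ref.coords + np.array([[0, 0, 0]] * 2 + [[30, 0, 0]] * 2))
        assert len(native_contacts((rec, lig_ref))) == 2
        assert fnat((rec, lig_model), (rec, lig_ref)) == pytest.approx(0.5)

    def test_contact_free_reference_is_degenerate(self):
        pair = two_residue_pair(30.0)
        with pytest.raises(DegenerateReferenceError):
            fnat(pair, pair)

    def test_literal_denominator_variant(self, ridge_dimer):
        ref = ridge_dimer.reference_complex()
        n_res = (len(set(ref[0].residue_keys()))
                 + len(set(ref[1].residue_keys())))
        expected = len(native_contacts(ref)) / n_res
        assert fnat(ref, ref, denominator="model_residues") == \
            pytest.approx(expected)


class TestSuperpose:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        t, rmsd = superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-8)

    def test_rigidly_rotated_copy(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(25, 3)) * 6
        R = Rotation.from_euler("zyx", [0.4, -1.0, 2.2]).as_matrix()
        moved = pts @ R.T + [3.0, -1.0, 7.0]
        _, rmsd = superpose(moved, pts)
        assert rmsd <= 1e-9

    def test_matches_quaternion_eigen_oracle(self):
        rng = np.random.default_rng(2)
        for trial in range(50):
            a = rng.normal(size=(50, 3)) * 5
            b = rng.normal(size=(50, 3)) * 5
            _, rmsd = superpose(a, b)
            _, _, oracle_rmsd = horn_superpose(a, b)
            assert rmsd == pytest.approx(oracle_rmsd, abs=1e-9)

    def test_too_few_points_degenerate(self):
        with pytest.raises(DegenerateSuperpositionError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_collinear_points_degenerate(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(DegenerateSuperpositionError):
            superpose(line, line)


class TestLigandRmsd:
    def test_identity_is_zero(self, ridge_dimer):
        ref = ridge_dimer.reference_complex()
        assert ligand_rmsd(ref, ref) == pytest.approx(0.0, abs=1e-9)

    def test_common_rigid_motion_removed_by_receptor_fit(self, ridge_dimer):
        rec, lig = ridge_dimer.reference_complex()
        t = RigidTransform(Rotation.from_euler("xyz", [0.2, 0.5, -0.9]).as_matrix(),
                           np.array([10.0, -4.0, 2.0]))
        moved = (apply_transform(rec, t), apply_transform(lig, t))
        assert ligand_rmsd(moved, (rec, lig)) == pytest.approx(0.0, abs=1e-6)

    def test_pure_ligand_translation_is_pythagorean(self, ridge_dimer):
        rec, lig = ridge_dimer.reference_complex()
        shifted = lig.with_coords(lig.coords + [3.0, 4.0, 0.0])
        assert ligand_rmsd((rec, shifted), (rec, lig)) == pytest.approx(5.0)

    def test_mismatched_residues_raise(self, ridge_dimer):
        rec, lig = ridge_dimer.reference_complex()
        truncated = lig.select(lig.residue_numbers > 3)
        with pytest.raises(CorrespondenceError):
            ligand_rmsd((rec, lig), (rec, truncated))


class TestInterfaceRmsd:
    def test_identity_is_zero(self, ridge_dimer):
        ref = ridge_dimer.reference_complex()
        assert interface_rmsd(ref, ref) == pytest.approx(0.0, abs=1e-9)

    def test_displacing_non_interface_residues_changes_nothing(self,
                                                               ridge_dimer):
        rec, lig = ridge_dimer.reference_complex()
        contacts = native_contacts((rec, lig), cutoff=10.0)
        lig_if = {l for _, l in contacts}
        far_mask = ~np.isin(lig.residue_keys(), list(lig_if))
        coords = lig.coords.copy()
        coords[far_mask] += [0.0, 200.0, 0.0]
        moved = lig.with_coords(coords)
        assert interface_rmsd((rec, moved), (rec, lig)) == \
            pytest.approx(0.0, abs=1e-9)

    def test_jittered_interface_matches_superposition_oracle(self,
                                                             ridge_dimer):
        rec, lig = ridge_dimer.reference_complex()
        rng = np.random.default_rng(8)
        jittered = lig.with_coords(lig.coords + rng.normal(0, 0.5,
                                                           lig.coords.shape))
        value = interface_rmsd((rec, jittered), (rec, lig))
        # oracle: collect the same interface C-alphas and superpose with the
        # independent quaternion-eigenvector method
        contacts = native_contacts((rec, lig), cutoff=10.0)
        rec_if = {r for r, _ in contacts}
        lig_if = {l for _, l in contacts}

        def if_calpha(s, keys):
            mask = s.calpha_mask() & np.isin(s.residue_keys(), list(keys))
            order = np.argsort(s.residue_keys()[mask])
            return s.coords[mask][order]

        mob = np.vstack([if_calpha(rec, rec_if), if_calpha(jittered, lig_if)])
        tgt = np.vstack([if_calpha(rec, rec_if), if_calpha(lig, lig_if)])
        _, _, oracle = horn_superpose(mob, tgt)
        assert value == pytest.approx(oracle, abs=1e-9)


class TestClassifyQuality:
    @pytest.mark.parametrize("metrics,expected", [
        ((0.05, 2.0, 1.0), Tier.INCORRECT),
        ((0.6, 0.9, 0.9), Tier.HIGH),
        ((0.2, 8.0, 3.5), Tier.ACCEPTABLE),
        ((0.4, 4.0, 1.5), Tier.INTERMEDIATE),
        ((0.05, 0.1, 0.1), Tier.INCORRECT),   # fnat gate applies first
        ((0.9, 12.0, 5.0), Tier.INCORRECT),   # joint RMSD gate despite fnat
        ((0.35, 12.0, 3.5), Tier.ACCEPTABLE),  # good fnat, poor geometry
    ])
    def test_examples(self, metrics, expected):
        assert classify_quality(*metrics) == expected

    def test_matches_truth_table_on_dense_grid(self):
        fnats = np.arange(0.0, 1.0001, 0.05)
        rmsds = np.arange(0.0, 12.001, 0.5)
        irmsds = np.arange(0.0, 5.001, 0.25)
        for f in fnats:
            for r in rmsds:
                for ir in irmsds:
                    assert str(classify_quality(f, r, ir)) == \
                        truth_table_tier(f, r, ir), (f, r, ir)

    def test_increasing_fnat_never_demotes(self):
        from hypothesis import given, settings, strategies as st

        @given(r=st.floats(0, 12), ir=st.floats(0, 5),
               f1=st.floats(0, 1), f2=st.floats(0, 1))
        @settings(max_examples=300, derandomize=True, deadline=None)
        def check(r, ir, f1, f2):
            lo, hi = sorted((f1, f2))
            assert classify_quality(hi, r, ir) >= classify_quality(lo, r, ir)

        check()


class TestDifficulty:
    @pytest.mark.parametrize("delta,label", [
        (0.5, "easy"), (1.7, "medium"), (3.0, "difficult"),
        (1.0, "medium"), (2.5, "medium"),
    ])
    def test_thresholds(self, delta, label):
        assert difficulty_from_delta(delta).label == label

    def test_identical_conformations_are_easy(self, ridge_dimer):
        ref = ridge_dimer.reference_complex()
        d = classify_difficulty(ref, ref)
        assert d.label == "easy"
        assert d.delta_interface_rmsd == pytest.approx(0.0, abs=1e-9)


class TestMetricInvariance:
    def test_common_rigid_transform_preserves_all_metrics(self, ridge_dimer):
        rec, lig = ridge_dimer.reference_complex()
        rng = np.random.default_rng(12)
        model_lig = lig.with_coords(lig.coords + rng.normal(0, 1.0,
                                                            lig.coords.shape))
        base = assess_model((rec, model_lig), (rec, lig))
        t = RigidTransform(Rotation.from_euler("xyz", [1.0, -0.3, 0.7]).as_matrix(),
                           np.array([7.0, 3.0, -6.0]))
        moved = assess_model(
            (apply_transform(rec, t), apply_transform(model_lig, t)),
            (apply_transform(rec, t), apply_transform(lig, t)))
        assert moved.fnat == pytest.approx(base.fnat, abs=1e-12)
        assert moved.ligand_rmsd == pytest.approx(base.ligand_rmsd, abs=1e-6)
        assert moved.interface_rmsd == pytest.approx(base.interface_rmsd,
                                                     abs=1e-6)
        assert moved.tier == base.tier


class TestReportTopN:
    def _result_from_poses(self, poses, scores):
        models = [ScoredPose(p, float(s), rank=i + 1)
                  for i, (p, s) in enumerate(zip(poses, scores))]
        return DockingResult(models=models)

    def test_all_far_decoys_are_incorrect(self, ridge_dimer):
        from tmdock import Pose
        tp = ridge_dimer.true_pose
        poses = [Pose(tp.tx + 60 + i, tp.ty - 50, tp.tz, tp.ax, tp.ay, tp.az,
                      tp.theta) for i in range(5)]
        result = self._result_from_poses(poses, [50 - i for i in range(5)])
        best, first, reports = report_top_n(
            result, ridge_dimer.receptor, ridge_dimer.ligand,
            ridge_dimer.reference_complex())
        assert best == Tier.INCORRECT
        assert first is None

    def test_first_success_rank_reported(self, ridge_dimer):
        from tmdock import Pose
        tp = ridge_dimer.true_pose
        far = Pose(tp.tx + 60, tp.ty - 50, tp.tz, tp.ax, tp.ay, tp.az,
                   tp.theta)
        poses = [far, far, tp, far, far, far, tp]
        result = self._result_from_poses(poses,
                                         [70 - i for i in range(len(poses))])
        best, first, reports = report_top_n(
            result, ridge_dimer.receptor, ridge_dimer.ligand,
            ridge_dimer.reference_complex())
        assert first == 3
        assert best == Tier.HIGH
        assert len(reports) == len(poses)

    def test_planted_near_native_at_rank_5(self, ridge_dimer):
        from tmdock import Pose
        tp = ridge_dimer.true_pose
        far = Pose(tp.tx + 60, tp.ty - 50, tp.tz, tp.ax, tp.ay, tp.az,
                   tp.theta)
        near = Pose(tp.tx + 0.8, tp.ty + 0.5, tp.tz, tp.ax, tp.ay, tp.az,
                    tp.theta)
        poses = [far] * 4 + [near] + [far] * 5
        result = self._result_from_poses(poses, list(range(100, 90, -1)))
        best, first, _ = report_top_n(
            result, ridge_dimer.receptor, ridge_dimer.ligand,
            ridge_dimer.reference_complex())
        assert best >= Tier.ACCEPTABLE
        assert first == 5

    def test_assessment_table_row_count(self, tmp_path, ridge_dimer):
        ref = ridge_dimer.reference_complex()
        reports = [assess_model(ref, ref)]
        path = tmp_path / "report.tsv"
        write_assessment_table(reports, path)
        assert len(path.read_text().splitlines()) == 2
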