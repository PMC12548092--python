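"""Helix geometry: helicity, axis fitting, superposition, comparison."""

import math

import numpy as np
import pytest

from akfray import helix as hx
from akfray.synthetic import gen_helix, gen_kinked_helix, _helix_torsions


@pytest.fixture(scope="module")
def ideal20():
    return hx.build_backbone(_helix_torsions(20))


class TestHelicity:
    def test_ideal_helix_fully_helical(self, ideal20):
        status = hx.assign_helicity(ideal20)
        assert all(v == "helical" for v in status.values())

    def test_extended_chain_has_no_helix(self):
        model = hx.build_backbone([(hx.PHI_EXT, hx.PSI_EXT)] * 20)
        status = hx.assign_helicity(model)
        assert not any(v == "helical" for v in status.values())

    @pytest.mark.parametrize("n_fray", [1, 2, 3, 4])
    def test_c_terminal_fraying_flags_exact_residues(self, n_fray):
        _, moved = gen_helix(16, n_fray=n_fray, include_core=False)
        status = hx.assign_helicity(moved, residue_range=(1, 16))
        non_helical = sorted(r for r, s in status.items() if s != "helical")
        assert non_helical == list(range(16 - n_fray + 1, 17))

    def test_n_terminal_fraying(self):
        _, moved = gen_helix(16, n_fray=3, terminus="N", include_core=False)
        status = hx.assign_helicity(moved, residue_range=(1, 16))
        non_helical = sorted(r for r, s in status.items() if s != "helical")
        assert non_helical == [1, 2, 3]

    def test_missing_residues_reported_unmodeled(self, ideal20):
        model = ideal20.copy()
        del model.chains["A"][10]
        status = hx.assign_helicity(model, residue_range=(1, 20))
        assert status[10] == "unmodeled"

    def test_helicity_agrees_with_torsion_classification(self):
        """H-bond helicity and a phi/psi window agree on >95% of residues of
        generated mixed sets."""
        agree = total = 0
        for n_fray in (0, 2, 4):
            _, model = gen_helix(18, n_fray=n_fray, include_core=False)
            status = hx.assign_helicity(model, residue_range=(1, 18))
            for r in range(1, 19):
                torsion_helical = r <= 18 - n_fray - (1 if n_fray else 0)
                total += 1
                agree += (status[r] == "helical") == torsion_helical
        assert agree / total > 0.95


class TestAxis:
    def test_parametric_helix_axis_along_z(self):
        """CA on an ideal cylinder helix (rise 1.5 A, twist 100 deg,
        radius 2.3 A) yield an axis within 0.5 deg of z."""
        k = np.arange(20)
        twist = np.radians(100.0) * k
        ca = np.column_stack(
            [2.3 * np.cos(twist), 2.3 * np.sin(twist), 1.5 * k]
        )
        axis = hx.fit_axis(ca)
        assert abs(axis.direction @ np.array([0.0, 0.0, 1.0])) > math.cos(math.radians(0.5))
        # residual wobble of the 4-CA window centers stays well below the
        # helix radius
        assert axis.goodness < 0.3

    def test_built_backbone_axis_matches_subsegment(self, ideal20):
        ca = np.array([ideal20.chains["A"][i].atoms["CA"] for i in range(1, 21)])
        full = hx.fit_axis(ca)
        sub = hx.fit_axis(ca[3:17])
        assert abs(full.direction @ sub.direction) > math.cos(math.radians(1.0))

    def test_equivariance_under_rotation(self, ideal20):
        ca = np.array([ideal20.chains["A"][i].atoms["CA"] for i in range(1, 21)])
        axis0 = hx.fit_axis(ca)
        theta = math.radians(37.0)
        rot = np.array(
            [[math.cos(theta), -math.sin(theta), 0],
             [math.sin(theta), math.cos(theta), 0],
             [0, 0, 1]]
        )
        axis1 = hx.fit_axis(ca @ rot.T)
        assert np.allclose(axis1.direction, rot @ axis0.direction, atol=1e-9)

    def test_random_coil_has_large_residual(self):
        rng = np.random.default_rng(2)
        pts = np.cumsum(rng.normal(0, 3.0, (20, 3)), axis=0)
        axis = hx.fit_axis(pts)
        assert axis.goodness > 1.0

    def test_too_few_residues_rejected(self):
        with pytest.raises(ValueError):
            hx.fit_axis(np.zeros((5, 3)))


class TestSuperpose:
    def test_self_superposition_is_identity(self, ideal20):
        rot, trans, rmsd, missing = hx.superpose(ideal20, ideal20, (1, 20))
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(rot, np.eye(3), atol=1e-9)
        assert np.allclose(trans, 0.0, atol=1e-9)
        assert not missing

    def test_rigid_motion_recovered_exactly(self, ideal20):
        theta = math.radians(25.0)
        rot_true = np.array(
            [[1, 0, 0],
             [0, math.cos(theta), -math.sin(theta)],
             [0, math.sin(theta), math.cos(theta)]]
        )
        t_true = np.array([3.0, -2.0, 7.0])
        moved = ideal20.transform(rot_true, t_true)
        rot, trans, rmsd, _ = hx.superpose(moved, ideal20, (1, 20))
        assert rmsd == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(rot, rot_true.T, atol=1e-9)

    def test_rmsd_invariant_under_global_motion_of_both(self, ideal20):
        rng = np.random.default_rng(1)
        jittered = ideal20.copy()
        for res in jittered.chains["A"].values():
            for a in res.atoms:
                res.atoms[a] = res.atoms[a] + rng.normal(0, 0.3, 3)
        _, _, rmsd0, _ = hx.superpose(jittered, ideal20, (1, 20))
        theta = math.radians(50.0)
        rot = np.array(
            [[math.cos(theta), 0, math.sin(theta)],
             [0, 1, 0],
             [-math.sin(theta), 0, math.cos(theta)]]
        )
        t = np.array([-4.0, 9.0, 1.0])
        _, _, rmsd1, _ = hx.superpose(jittered.transform(rot, t), ideal20.transform(rot, t), (1, 20))
        assert rmsd1 == pytest.approx(rmsd0, abs=1e-9)

    def test_proper_rotation_enforced(self, ideal20):
        rot, *_ = hx.superpose(ideal20, ideal20, (1, 20))
        assert np.linalg.det(rot) == pytest.approx(1.0)

    def test_too_few_pairs_rejected(self, ideal20):
        empty = hx.StructureModel(chains={"A": {}})
        with pytest.raises(ValueError):
            hx.superpose(ideal20, empty, (1, 20))


class TestCompareHelix:
    def test_identity_comparison(self):
        ref, moved = gen_helix(16, 0.0, 0.0, 0)
        cmp = hx.compare_helix(ref, moved, (1, 16), (101, 120))
        # arccos amplifies float rounding near identity; 1e-4 deg is still
        # a numerically exact zero for this purpose
        assert cmp.tilt_deg == pytest.approx(0.0, abs=1e-4)
        assert cmp.translation_ang == pytest.approx(0.0, abs=1e-7)
        assert cmp.frayed_n_terminal == [] and cmp.frayed_c_terminal == []
        assert cmp.core_rmsd_ang == pytest.approx(0.0, abs=1e-9)

    def test_programmed_geometry_recovered(self):
        ref, moved = gen_helix(16, tilt_deg=21.0, translation_ang=5.8, n_fray=3)
        cmp = hx.compare_helix(ref, moved, (1, 16), (101, 120))
        assert cmp.tilt_deg == pytest.approx(21.0, abs=0.5)
        assert cmp.translation_ang == pytest.approx(5.8, abs=0.05)
        assert cmp.frayed_c_terminal == [14, 15, 16]

    def test_recovery_with_coordinate_noise_across_seeds(self):
        for seed in range(5):
            ref, moved = gen_helix(
                16, tilt_deg=21.0, translation_ang=5.8, n_fray=3,
                seed=seed, coord_noise_ang=0.01,
            )
            cmp = hx.compare_helix(ref, moved, (1, 16), (101, 120))
            assert cmp.tilt_deg == pytest.approx(21.0, abs=0.5)
            assert cmp.translation_ang == pytest.approx(5.8, abs=0.05)
            assert cmp.frayed_c_terminal == [14, 15, 16]

    def test_missing_helix_raises(self):
        ref, moved = gen_helix(16, 0.0, 0.0, 0)
        for n in range(1, 17):
            del moved.chains["A"][n]
        with pytest.raises(ValueError):
            hx.compare_helix(ref, moved, (1, 16), (101, 120))


class TestBendAngle:
    def test_straight_helix_is_straight(self):
        model = hx.build_backbone(_helix_torsions(24))
        assert hx.bend_angle(model, (1, 24), 12) == pytest.approx(0.0, abs=1.0)

    def test_programmed_kink_recovered(self):
        model = gen_kinked_helix(24, kink_deg=25.0, split=12)
        assert hx.bend_angle(model, (1, 24), 12) == pytest.approx(25.0, abs=1.0)

    def test_side_label_symmetry(self):
        model = gen_kinked_helix(24, kink_deg=18.0, split=12)
        # reverse residue numbering: the N/C labels swap but the angle must not
        rev = hx.StructureModel()
        rev.chains["A"] = {25 - n: res for n, res in model.chains["A"].items()}
        a = hx.bend_angle(model, (1, 24), 12)
        b = hx.bend_angle(rev, (1, 24), 13)
        assert a == pytest.approx(b, abs=0.5)

    def test_short_side_rejected(self):
        model = hx.build_backbone(_helix_torsions(14))
        with pytest.raises(ValueError):
            hx.bend_angle(model, (1, 14), 3)


class TestStructureIO:
    def test_pdb_round_trip(self, tmp_path):
        ref, _ = gen_helix(12, include_core=False)
        path = tmp_path / "helix.pdb"
        hx.write_pdb(ref, path)
        back = hx.read_structure(path)
        for n, res in ref.chains["A"].items():
            for a, xyz in res.atoms.items():
                assert np.allclose(back.chains["A"][n].atoms[a], xyz, atol=1e-2)

    def test_helicity_survives_pdb_round_trip(self, tmp_path):
        _, moved = gen_helix(16, n_fray=3, include_core=False)
        path = tmp_path / "frayed.pdb"
        hx.write_pdb(moved, path)
        back = hx.read_structure(path)
        status = hx.assign_helicity(back, residue_range=(1, 16))
        assert sorted(r for r, s in status.items() if s != "helical") == [14, 15, 16]
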