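"""Geometry descriptors: torsions, centroid distances, superposition, RMSD,
Z-distance/Z-angle, and whole-matrix extraction."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gpcrswitch import synthetic
from gpcrswitch.descriptors import (centroid_distance, chi_angles, dihedral,
                                    extract_features, min_polar_distance,
                                    rmsd_to_reference, superpose,
                                    z_distance_angle)
from gpcrswitch.structures import AtomSelector, StructureModel, TrajectoryHandle

from conftest import random_feature_vector


def brute_dihedral(p1, p2, p3, p4):
    """Independent oracle: atan2 of cross/dot in the b2 frame."""
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    x = np.dot(n1, n2)
    a = np.degrees(np.arctan2(y, x))
    return 180.0 if a <= -180.0 else a


def _atoms(coords, names=None, elements=None, resids=None, resnames=None):
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    return StructureModel(
        names=np.array(names or [f"X{i}" for i in range(n)], dtype=object),
        elements=np.array(elements or ["C"] * n, dtype=object),
        resids=np.array(resids if resids is not None else np.arange(1, n + 1)),
        resnames=np.array(resnames or ["UNK"] * n, dtype=object),
        segids=np.array(["A"] * n, dtype=object),
        coords=coords,
    )


class TestDihedral:
    def test_planar_cis_is_zero(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]) == pytest.approx(0.0, abs=1e-12)

    def test_planar_trans_is_180(self):
        assert dihedral([0, 1, 0], [0, 0, 0], [1, 0, 0], [1, -1, 0]) == pytest.approx(180.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(1000):
            pts = rng.normal(size=(4, 3)) * 3
            try:
                got = dihedral(*pts)
            except ValueError:
                continue
            want = brute_dihedral(*pts)
            assert abs((got - want + 180) % 360 - 180) < 1e-9

    def test_collinear_raises(self):
        with pytest.raises(ValueError):
            dihedral([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0])


class TestChiAngles:
    def _model_at(self, chi1, chi2):
        f = {d: synthetic.preset("inactive_apo").basins[0].means[d]
             for d in synthetic.BASE_DOFS}
        f["chi1_w6x48"], f["chi2_w6x48"] = chi1, chi2
        return synthetic.build_structure(f)

    def test_round_trip_with_builder(self):
        m = self._model_at(60.0, 50.0)
        chi1, chi2 = chi_angles(m, AtomSelector(bw="6x48", segid="R"),
                                synthetic.toy_bw_map())
        assert chi1 == pytest.approx(60.0, abs=1e-6)
        assert chi2 == pytest.approx(50.0, abs=1e-6)

    def test_alternative_state_window(self):
        # the alternative toggle rotamer parks chi1 between 30 and 60 deg
        m = self._model_at(45.0, 100.0)
        chi1, _ = chi_angles(m, AtomSelector(bw="6x48", segid="R"),
                             synthetic.toy_bw_map())
        assert 30.0 <= chi1 <= 60.0

    def test_ring_flip_changes_chi2_by_180(self):
        f = {d: synthetic.preset("inactive_apo").basins[0].means[d]
             for d in synthetic.BASE_DOFS}
        f["chi2_f6x44"] = 30.0
        a = synthetic.build_structure(f)
        f["chi2_f6x44"] = 30.0 - 180.0
        b = synthetic.build_structure(f)
        bw = synthetic.toy_bw_map()
        _, chi2a = chi_angles(a, AtomSelector(bw="6x44", segid="R"), bw)
        _, chi2b = chi_angles(b, AtomSelector(bw="6x44", segid="R"), bw)
        assert (chi2a - chi2b) % 360 == pytest.approx(180.0, abs=1e-6)

    def test_missing_atom_named_in_error(self):
        m = _atoms([[0, 0, 0], [1, 0, 0]], names=["N", "CA"],
                   resnames=["TRP", "TRP"], resids=[7, 7])
        with pytest.raises(ValueError, match="CB"):
            chi_angles(m, AtomSelector(resid_range=(7, 7)))


class TestCentroidDistance:
    def test_two_single_atoms(self):
        m = _atoms([[0, 0, 0], [1, 0, 0]])
        d = centroid_distance(m, AtomSelector(resid_range=(1, 1)),
                              AtomSelector(resid_range=(2, 2)))
        assert d == pytest.approx(1.0)

    def test_hand_centroid(self):
        m = _atoms([[0, 0, 0], [2, 0, 0], [5, 0, 0]], resids=[1, 1, 2])
        d = centroid_distance(m, AtomSelector(resid_range=(1, 1)),
                              AtomSelector(resid_range=(2, 2)))
        assert d == pytest.approx(4.0)

    def test_hydrogens_excluded_from_centroid(self):
        m = _atoms([[0, 0, 0], [100, 0, 0], [3, 0, 0]],
                   elements=["C", "H", "C"], resids=[1, 1, 2])
        d = centroid_distance(m, AtomSelector(resid_range=(1, 1), exclude_caps=False),
                              AtomSelector(resid_range=(2, 2), exclude_caps=False))
        assert d == pytest.approx(3.0)

    def test_bulge_ordering_across_presets(self):
        # the G-protein-ideal basin has the deeper TM5 distortion
        barr = synthetic.preset("beta_arrestin_ideal").basins[0].means
        gp = synthetic.preset("g_protein_ideal").basins[0].means
        da = centroid_distance(synthetic.build_structure(barr),
                               AtomSelector(bw="5x46", group="heavy", segid="R"),
                               AtomSelector(bw="7x41", group="heavy", segid="R"),
                               synthetic.toy_bw_map())
        dg = centroid_distance(synthetic.build_structure(gp),
                               AtomSelector(bw="5x46", group="heavy", segid="R"),
                               AtomSelector(bw="7x41", group="heavy", segid="R"),
                               synthetic.toy_bw_map())
        assert da > dg


class TestMinPolarDistance:
    def test_single_pair(self):
        m = _atoms([[0, 0, 0], [2.8, 0, 0]], names=["O1", "OG"],
                   elements=["O", "O"], resids=[1, 2])
        d = min_polar_distance(m, AtomSelector(resid_range=(1, 1)),
                               AtomSelector(resid_range=(2, 2)))
        assert d == pytest.approx(2.8)

    def test_minimum_over_enumerated_pairs(self):
        m = _atoms([[0, 0, 0], [0, 5, 0], [3.1, 0, 0], [0, 9, 0]],
                   names=["O1", "N1", "OG", "ND2"],
                   elements=["O", "N", "O", "N"], resids=[1, 1, 2, 2])
        d = min_polar_distance(m, AtomSelector(resid_range=(1, 1)),
                               AtomSelector(resid_range=(2, 2)))
        # pairs: 3.1, 9.0(=|5-(-4)|...), etc. smallest is 3.1
        assert d == pytest.approx(3.1)

    def test_carbon_only_ligand_raises(self):
        m = _atoms([[0, 0, 0], [3, 0, 0]], names=["C1", "OG"],
                   elements=["C", "O"], resids=[1, 2])
        with pytest.raises(ValueError, match="polar"):
            min_polar_distance(m, AtomSelector(resid_range=(1, 1)),
                               AtomSelector(resid_range=(2, 2)))


class TestSuperpose:
    def test_identity(self, rng):
        pts = rng.normal(size=(10, 3))
        rot, t, rmsd = superpose(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-12)
        assert rmsd == pytest.approx(0.0, abs=1e-12)

    def test_recovers_constructed_transform(self, rng):
        pts = rng.normal(size=(12, 3))
        true_rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        moved = pts @ true_rot.T + np.array([1.0, -2.0, 3.0])
        rot, t, rmsd = superpose(pts, moved)
        np.testing.assert_allclose(rot, true_rot, atol=1e-9)
        assert rmsd == pytest.approx(0.0, abs=1e-9)

    def test_mirror_image_not_matched(self, rng):
        pts = rng.normal(size=(10, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, rmsd = superpose(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0)
        assert rmsd > 0.1

    def test_matches_scipy_oracle(self, rng):
        for _ in range(200):
            a = rng.normal(size=(8, 3))
            b = rng.normal(size=(8, 3))
            rot, _, rmsd = superpose(a, b)
            r_sp, rssd = Rotation.align_vectors(b - b.mean(0), a - a.mean(0))
            want = rssd / np.sqrt(len(a))
            assert rmsd == pytest.approx(want, abs=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRMSD:
    def _pair(self, rng, shift):
        base = rng.normal(size=(20, 3))
        names = np.array([f"A{i}" for i in range(20)], dtype=object)
        mk = lambda c: StructureModel(
            names=names, elements=np.array(["C"] * 20, dtype=object),
            resids=np.arange(20), resnames=np.array(["ALA"] * 20, dtype=object),
            segids=np.array(["R"] * 20, dtype=object), coords=c)
        moved = base.copy()
        moved[10:] += shift
        return mk(base), mk(moved)

    def test_frame_equals_reference(self, rng):
        ref, _ = self._pair(rng, 0.0)
        sel = AtomSelector(group="all")
        assert rmsd_to_reference(ref, ref, sel, sel) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_displacement(self, rng):
        ref, moved = self._pair(rng, np.array([1.0, 0, 0]))
        fit = AtomSelector(resid_range=(0, 9))        # unmoved half
        calc = AtomSelector(resid_range=(10, 19))     # displaced half
        got = rmsd_to_reference(moved, ref, fit, calc)
        assert got == pytest.approx(1.0, abs=1e-9)

    def test_symmetry(self, rng):
        ref, moved = self._pair(rng, rng.normal(size=3) * 0.3)
        sel = AtomSelector(group="all")
        a = rmsd_to_reference(moved, ref, sel, sel)
        b = rmsd_to_reference(ref, moved, sel, sel)
        assert a == pytest.approx(b, abs=1e-9)


class TestZDistanceAngle:
    def _model(self, rec_z, ifc, tail):
        coords = [[0, 0, rec_z], [0, 0, rec_z], list(ifc), list(tail)]
        return _atoms(coords, names=["CA", "CA", "CA", "CA"],
                      resids=[1, 2, 3, 4])

    def _sels(self):
        return (AtomSelector(resid_range=(1, 2)),
                AtomSelector(resid_range=(3, 3)),
                AtomSelector(resid_range=(4, 4)))

    def test_equal_heights_give_zero(self):
        m = self._model(10.0, (5, 0, 10), (9, 0, 10))
        zd, za = z_distance_angle(m, *self._sels())
        assert zd == pytest.approx(0.0)
        assert za == pytest.approx(0.0)

    def test_arcsin_geometry(self):
        m = self._model(10.0, (5, 0, 0), (5, 0, 1))
        _, za = z_distance_angle(m, *self._sels())
        assert za == pytest.approx(90.0)
        m = self._model(10.0, (5, 0, 0), (6, 0, 1))
        zd, za = z_distance_angle(m, *self._sels())
        assert za == pytest.approx(45.0)
        assert zd == pytest.approx(10.0)

    def test_brute_force_oracle(self, rng):
        for _ in range(1000):
            rec_z = rng.normal() * 5
            ifc = rng.normal(size=3) * 5
            tail = ifc + rng.normal(size=3)
            m = self._model(rec_z, ifc, tail)
            zd, za = z_distance_angle(m, *self._sels())
            v = tail - ifc
            assert zd == pytest.approx(rec_z - ifc[2], abs=1e-9)
            assert za == pytest.approx(
                np.degrees(np.arcsin(v[2] / np.linalg.norm(v))), abs=1e-6)


class TestExtractFeatures:
    def test_basin_means_recovered(self, toy_catalogue, toy_bw):
        spec = synthetic.preset("beta_arrestin_ideal", n_frames=200, seed=12)
        fm, _ = synthetic.sample_features(spec)
        traj = synthetic.build_trajectory(fm)
        out = extract_features(traj, toy_catalogue, bw_map=toy_bw)
        basin = spec.basins[0]
        for d in ("tm26", "tm37", "dist_wn", "ionic_lock"):
            # extraction reproduces the sampled values exactly ...
            assert abs(out.values[d].mean() - fm.values[d].mean()) < 1e-9
            # ... and the sample recovers the basin mean statistically
            se = basin.sds[d] / np.sqrt(200)
            assert abs(out.values[d].mean() - basin.means[d]) < 3 * se + 1e-9

    def test_single_frame_matrix(self, toy_catalogue, toy_bw):
        spec = synthetic.preset("inactive_apo", n_frames=1, seed=1)
        fm, _ = synthetic.sample_features(spec)
        traj = synthetic.build_trajectory(fm)
        out = extract_features(traj, toy_catalogue, bw_map=toy_bw)
        assert out.values.shape == (1, len(toy_catalogue))

    def test_column_removal_leaves_others_unchanged(self, toy_catalogue, toy_bw):
        spec = synthetic.preset("inactive_apo", n_frames=3, seed=9)
        fm, _ = synthetic.sample_features(spec)
        traj = synthetic.build_trajectory(fm)
        full = extract_features(traj, toy_catalogue, bw_map=toy_bw)
        reduced = extract_features(traj, toy_catalogue[:-1], bw_map=toy_bw)
        assert toy_catalogue[-1].name not in reduced.values
        np.testing.assert_array_equal(
            full.values[reduced.dof_names].to_numpy(),
            reduced.values.to_numpy())

    def test_failure_reports_frame_and_dof(self, toy_catalogue):
        spec = synthetic.preset("inactive_apo", n_frames=1, seed=1)
        fm, _ = synthetic.sample_features(spec)
        traj = synthetic.build_trajectory(fm)
        with pytest.raises(RuntimeError, match="frame 0"):
            extract_features(traj, toy_catalogue, bw_map=None)

    def test_distances_invariant_under_rigid_motion(self, rng, toy_catalogue,
                                                    toy_bw):
        vec = random_feature_vector(rng)
        m = synthetic.build_structure(vec)
        rot = Rotation.random(random_state=3).as_matrix()
        moved = m.with_coords(m.coords @ rot.T + np.array([5.0, -3.0, 8.0]))
        t1 = TrajectoryHandle(m, m.coords[None])
        t2 = TrajectoryHandle(moved, moved.coords[None])
        non_z = [d for d in toy_catalogue
                 if d.kind not in ("z-distance", "z-angle")]
        a = extract_features(t1, non_z, bw_map=toy_bw).values.iloc[0]
        b = extract_features(t2, non_z, bw_map=toy_bw).values.iloc[0]
        for name in a.index:
            diff = a[name] - b[name]
            if name.startswith("chi"):
                diff = (diff + 180) % 360 - 180
            assert abs(diff) < 1e-8

    def test_z_dofs_invariant_under_rotation_about_z(self, rng, toy_catalogue,
                                                     toy_bw):
        vec = random_feature_vector(rng)
        m = synthetic.build_structure(vec)
        rot = Rotation.from_euler("z", 73, degrees=True).as_matrix()
        moved = m.with_coords(m.coords @ rot.T + np.array([2.0, 7.0, -4.0]))
        zdofs = [d for d in toy_catalogue if d.kind in ("z-distance", "z-angle")]
        t1 = TrajectoryHandle(m, m.coords[None])
        t2 = TrajectoryHandle(moved, moved.coords[None])
        a = extract_features(t1, zdofs, bw_map=toy_bw).values.iloc[0]
        b = extract_features(t2, zdofs, bw_map=toy_bw).values.iloc[0]
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)
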