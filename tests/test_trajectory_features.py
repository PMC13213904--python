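import itertools

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from metastate import features, geometry, trajectory
from metastate.trajectory import (
    Trajectory,
    TrajectoryDataError,
    TrajectoryFormatError,
    read_structure_ensemble,
    superpose_and_rmsf,
    write_pdb,
)


def make_traj(coords, names, elements, res_ids, res_names):
    return Trajectory(np.asarray(coords, dtype=float), names, elements, res_ids, res_names)


def independent_dihedral(p0, p1, p2, p3):
    """Second, independent torsion implementation (projection onto the plane
    normal to the central bond, explicit atan2 on 2-D components)."""
    b = p2 - p1
    b = b / np.linalg.norm(b)
    u = p0 - p1
    v = p3 - p2
    u_perp = u - np.dot(u, b) * b
    v_perp = v - np.dot(v, b) * b
    x = np.dot(u_perp, v_perp)
    y = np.dot(np.cross(b, u_perp), v_perp)
    return -np.degrees(np.arctan2(y, x))


class TestReadEnsemble:
    def test_single_model_round_trip(self, tmp_path, chain78):
        path = tmp_path / "single.pdb"
        write_pdb(chain78, path)
        back = read_structure_ensemble(path)
        assert back.n_frames == 1
        assert back.n_atoms == chain78.n_atoms
        assert np.allclose(back.coords, chain78.coords, atol=2e-4)  # PDB precision
        assert list(back.res_names) == list(chain78.res_names)

    def test_multi_model_shares_metadata(self, tmp_path, helix):
        rng = np.random.default_rng(0)
        multi = Trajectory(
            np.concatenate([helix.coords + 0.01 * rng.standard_normal(helix.coords.shape)
                            for _ in range(3)]),
            helix.atom_names, helix.elements, helix.res_ids, helix.res_names)
        path = tmp_path / "multi.pdb"
        write_pdb(multi, path)
        back = read_structure_ensemble(path)
        assert back.n_frames == 3
        assert list(back.atom_names) == list(helix.atom_names)

    def test_inconsistent_model_raises(self, tmp_path, helix):
        path = tmp_path / "bad.pdb"
        write_pdb(Trajectory(np.repeat(helix.coords, 2, axis=0), helix.atom_names,
                             helix.elements, helix.res_ids, helix.res_names), path)
        lines = path.read_text().splitlines()
        # drop one ATOM line from the second model
        second_model = [i for i, l in enumerate(lines) if l.startswith("MODEL")][1]
        atom_line = next(i for i in range(second_model, len(lines))
                         if lines[i].startswith("ATOM"))
        del lines[atom_line]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrajectoryFormatError):
            read_structure_ensemble(path)

    def test_trajectory_topology_reader_contract(self, tmp_path, helix):
        pytest.importorskip("mdtraj")
        path = tmp_path / "ens.pdb"
        write_pdb(helix, path)
        back = read_structure_ensemble(path, format="trajectory+topology",
                                       topology=path)
        assert back.n_frames == helix.n_frames
        assert back.n_atoms == helix.n_atoms
        assert np.allclose(back.coords, helix.coords, atol=2e-4)

    def test_empty_file_raises(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("")
        with pytest.raises((TrajectoryFormatError, ValueError)):
            read_structure_ensemble(path)


class TestPairDistances:
    def test_exhaustive_counts(self, chain78):
        assert features.pair_distance_features(chain78).n_features == 3003
        assert features.pair_distance_features(
            chain78, selection="hydrophobic").n_features == 903

    def test_exhaustive_count_formula(self, chain78):
        # n residues -> n(n-1)/2 columns for any residue subset
        sub = [int(r) for r in chain78.residue_ids[:10]]
        fm = features.pair_distance_features(chain78, pairs=list(
            itertools.combinations(sub, 2)))
        assert fm.n_features == 10 * 9 // 2

    def test_known_com_distance(self):
        # two 1-atom "side chains" at (0,0,0) and (0,0,1.2)
        traj = make_traj(
            [[[0, 0, 0], [0, 0, 0.01], [0, 0, 1.2], [0, 0, 1.21]]],
            ["CA", "CB", "CA", "CB"], ["C"] * 4, [1, 1, 2, 2], ["ALA"] * 4)
        fm = features.pair_distance_features(traj, pairs=[(1, 2)], mode="sidechain-com")
        assert fm.values[0, 0] == pytest.approx(1.2, abs=1e-12)

    def test_glycine_com_falls_back_to_calpha(self, chain78):
        gly = next(int(r) for r in chain78.residue_ids
                   if chain78.residue_name(r) == "GLY")
        com = features.sidechain_com(chain78, gly)
        ca = chain78.coords[:, chain78.atom_index(gly, "CA")]
        assert np.allclose(com, ca)

    def test_symmetric_in_pair_order(self, chain78):
        i, j = (int(r) for r in chain78.residue_ids[[4, 39]])
        a = features.pair_distance_features(chain78, pairs=[(i, j)])
        b = features.pair_distance_features(chain78, pairs=[(j, i)])
        assert np.allclose(a.values, b.values)

    def test_calpha_mode_matches_direct(self, chain78):
        i, j = (int(r) for r in chain78.residue_ids[[2, 59]])
        fm = features.pair_distance_features(chain78, pairs=[(i, j)], mode="calpha")
        d = np.linalg.norm(chain78.coords[0, chain78.atom_index(i, "CA")]
                           - chain78.coords[0, chain78.atom_index(j, "CA")])
        assert fm.values[0, 0] == pytest.approx(d, abs=1e-12)


class TestFeatureMatrixIO:
    def test_csv_sidecar_round_trip(self, tmp_path, chain78):
        r = chain78.residue_ids
        fm = features.pair_distance_features(
            chain78, pairs=[(int(r[2]), int(r[59])), (int(r[4]), int(r[39]))],
            mode="calpha")
        path = tmp_path / "features.csv"
        fm.write_csv(path)
        back = features.FeatureMatrix.read_csv(path)
        assert back.labels == fm.labels
        assert back.units == fm.units
        assert np.allclose(back.values, fm.values)


class TestBackboneTorsions:
    def test_column_count(self, chain78):
        assert features.backbone_torsion_features(chain78).n_features == 308

    def test_trans_psi_encoding(self, extended):
        fm = features.backbone_torsion_features(extended)
        cos_cols = [i for i, l in enumerate(fm.labels) if l.startswith("cos_psi")]
        sin_cols = [i for i, l in enumerate(fm.labels) if l.startswith("sin_psi")]
        assert np.allclose(fm.values[0, cos_cols], -1.0, atol=1e-9)
        assert np.allclose(fm.values[0, sin_cols], 0.0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_dihedral_against_independent_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.standard_normal((4, 3))
        got = geometry.dihedral(*pts)
        expected = independent_dihedral(*pts)
        assert float(got) == pytest.approx(expected, abs=1e-9)

    def test_dihedral_sign_flips_under_mirror(self):
        rng = np.random.default_rng(3)
        pts = rng.standard_normal((4, 3))
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        a = float(geometry.dihedral(*pts))
        b = float(geometry.dihedral(*mirrored))
        assert a == pytest.approx(-b, abs=1e-9)

    def test_missing_backbone_atom_names_residue(self, helix):
        keep = ~((helix.res_ids == 5) & (helix.atom_names == "CA"))
        broken = Trajectory(helix.coords[:, keep], helix.atom_names[keep],
                            helix.elements[keep], helix.res_ids[keep],
                            helix.res_names[keep])
        with pytest.raises(TrajectoryDataError, match="5"):
            features.backbone_torsion_features(broken)


def _fake_ring_pair(angle_deg):
    """Two PHE-like rings whose planes meet at the requested angle."""
    hexagon = np.array([[np.cos(t), np.sin(t), 0.0]
                        for t in np.linspace(0, 2 * np.pi, 6, endpoint=False)]) * 0.14
    rot = Rotation.from_euler("x", angle_deg, degrees=True).as_matrix()
    ring2 = hexagon @ rot.T + np.array([1.0, 0, 0])
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    coords = np.vstack([hexagon, ring2])[None]
    return make_traj(coords, names * 2, ["C"] * 12, [1] * 6 + [2] * 6, ["PHE"] * 12)


class TestAngularDescriptors:
    @pytest.mark.parametrize("angle,expected", [(0, 0), (90, 90), (120, 60)])
    def test_ring_plane_angles(self, angle, expected):
        traj = _fake_ring_pair(angle)
        fm = features.angular_descriptors(traj, ring_pairs=[(1, 2)])
        assert fm.values[0, 0] == pytest.approx(expected, abs=1e-6)

    def test_ring_angle_invariant_to_atom_ordering(self):
        traj = _fake_ring_pair(35.0)
        perm = np.concatenate([np.random.default_rng(1).permutation(6),
                               6 + np.random.default_rng(2).permutation(6)])
        shuffled = make_traj(traj.coords[:, perm], traj.atom_names[perm],
                             traj.elements[perm], traj.res_ids[perm],
                             traj.res_names[perm])
        a = features.angular_descriptors(traj, ring_pairs=[(1, 2)]).values
        b = features.angular_descriptors(shuffled, ring_pairs=[(1, 2)]).values
        assert np.allclose(a, b, atol=1e-9)

    def test_planar_cis_quadruple_is_zero(self):
        coords = np.array([[[0, 1, 0], [0, 0, 0], [1, 0, 0], [1, 1, 0]]], dtype=float)
        traj = make_traj(coords, ["CA"] * 4, ["C"] * 4, [1, 2, 3, 4], ["ALA"] * 4)
        fm = features.angular_descriptors(traj, quads=[(1, 2, 3, 4)])
        assert fm.values[0, 0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_invariance(self, chain78):
        R = Rotation.from_euler("zyx", [31, -57, 112], degrees=True).as_matrix()
        t = np.array([1.7, -0.4, 2.2])
        moved = Trajectory(chain78.coords @ R.T + t, chain78.atom_names,
                           chain78.elements, chain78.res_ids, chain78.res_names)
        quads = [tuple(int(r) for r in chain78.residue_ids[[9, 19, 39, 59]])]
        rings = [(92, 134)]
        a = features.angular_descriptors(chain78, quads=quads, ring_pairs=rings).values
        b = features.angular_descriptors(moved, quads=quads, ring_pairs=rings).values
        assert np.allclose(a, b, atol=1e-9)

    def test_incomplete_ring_raises(self):
        traj = _fake_ring_pair(10.0)
        keep = np.arange(traj.n_atoms) != 2
        broken = make_traj(traj.coords[:, keep], traj.atom_names[keep],
                           traj.elements[keep], traj.res_ids[keep],
                           traj.res_names[keep])
        with pytest.raises(TrajectoryDataError):
            features.angular_descriptors(broken, ring_pairs=[(1, 2)])


class TestSuperposeAndRMSF:
    def test_identical_frames_zero(self, helix):
        traj = Trajectory(np.repeat(helix.coords, 4, axis=0), helix.atom_names,
                          helix.elements, helix.res_ids, helix.res_names)
        _, rmsd_vals, rmsf = superpose_and_rmsf(
            traj, helix.coords[0], trajectory.calpha_indices(helix))
        assert np.allclose(rmsd_vals, 0.0, atol=1e-12)
        assert np.allclose(rmsf, 0.0, atol=1e-12)

    def test_rigid_copy_superposes_exactly(self, helix):
        R = Rotation.from_euler("xyz", [10, 75, -33], degrees=True).as_matrix()
        moved = Trajectory(helix.coords @ R.T + np.array([3.0, -1.0, 0.5]),
                           helix.atom_names, helix.elements, helix.res_ids,
                           helix.res_names)
        _, rmsd_vals, _ = superpose_and_rmsf(
            moved, helix.coords[0], trajectory.calpha_indices(helix))
        assert rmsd_vals[0] <= 1e-9

    def test_hand_computed_rmsf(self):
        # 9 anchor atoms pin the superposition; the probe atom moves +-0.1 nm
        rng = np.random.default_rng(0)
        base = rng.standard_normal((10, 3))
        f1 = base.copy()
        f2 = base.copy()
        f1[9, 2] += 0.1
        f2[9, 2] -= 0.1
        traj = make_traj(np.stack([f1, f2]), ["CA"] * 10, ["C"] * 10,
                         np.arange(1, 11), ["ALA"] * 10)
        _, _, rmsf = superpose_and_rmsf(traj, base, np.arange(9))
        assert rmsf[9] == pytest.approx(0.1, abs=1e-6)
        assert np.all(rmsf[:9] < 1e-6)

    def test_superposition_never_increases_rmsd(self, helix):
        rng = np.random.default_rng(5)
        noisy = Trajectory(helix.coords + 0.05 * rng.standard_normal(helix.coords.shape),
                           helix.atom_names, helix.elements, helix.res_ids,
                           helix.res_names)
        R = Rotation.from_euler("z", 40, degrees=True).as_matrix()
        moved = Trajectory(noisy.coords @ R.T + 1.0, noisy.atom_names, noisy.elements,
                           noisy.res_ids, noisy.res_names)
        sel = trajectory.calpha_indices(helix)
        unaligned = geometry.rmsd(moved.coords[0, sel], helix.coords[0, sel])
        _, rmsd_vals, _ = superpose_and_rmsf(moved, helix.coords[0], sel)
        assert rmsd_vals[0] <= unaligned + 1e-12

    def test_too_few_atoms_raises(self, helix):
        with pytest.raises(TrajectoryDataError):
            superpose_and_rmsf(helix, helix.coords[0], np.array([0, 1]))
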