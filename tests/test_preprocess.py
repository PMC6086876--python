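"""Selection language, centering, Kabsch superposition, stripping."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import surfchannel as sc
from surfchannel.errors import AlignmentError, SelectionError


def _toy_traj(coords_per_frame, atoms=None):
    coords = np.asarray(coords_per_frame, dtype=float)
    n_atoms = coords.shape[1]
    if atoms is None:
        atoms = [
            sc.AtomRecord(i + 1, "CA", "ALA", "A", i + 1, *coords[0, i])
            for i in range(n_atoms)
        ]
    return sc.Trajectory(sc.Structure(atoms), coords)


class TestSelection:
    @pytest.mark.parametrize(
        "expr, expected",
        [
            ("resid 138-140", {138, 139, 140}),
            ("resid 5", {5}),
            ("resid 1-3 or resid 10", {1, 2, 3, 10}),
        ],
    )
    def test_resid_expressions(self, expr, expected, small_system):
        _, structure, _, _ = small_system
        idx = sc.select(structure, expr)
        assert {structure.atoms[i].residue_number for i in idx} == expected

    def test_conjunction_and_type(self, small_system):
        _, structure, _, _ = small_system
        idx = sc.select(structure, "substrate and type aha")
        assert all(
            structure.atoms[i].substrate_type is sc.SubstrateType.AHA_LIKE for i in idx
        )
        assert len(idx) == 20 * 22

    def test_indices_sorted_and_deterministic(self, small_system):
        _, structure, _, _ = small_system
        idx = sc.select(structure, "protein or substrate")
        assert idx == sorted(idx)
        assert idx == sc.select(structure, "protein or substrate")

    def test_empty_selection_raises(self, small_system):
        _, structure, _, _ = small_system
        with pytest.raises(SelectionError):
            sc.select(structure, "resname ZZZ")

    def test_unknown_keyword_raises(self, small_system):
        _, structure, _, _ = small_system
        with pytest.raises(SelectionError):
            sc.select(structure, "backbone")


class TestCenterOnSelection:
    def test_single_atom_to_origin(self):
        traj = _toy_traj([[[5.0, 5.0, 5.0]]])
        out = sc.center_on_selection(traj, "all")
        np.testing.assert_allclose(out.frames[0, 0], [0, 0, 0], atol=1e-12)

    def test_two_atom_centroid_to_origin(self):
        traj = _toy_traj([[[1.0, 0, 0], [3.0, 0, 0]]])
        out = sc.center_on_selection(traj, "all")
        np.testing.assert_allclose(out.frames[0], [[-1, 0, 0], [1, 0, 0]], atol=1e-12)

    def test_anchor_residues_centroid_at_origin_every_frame(self, small_system):
        _, _, _, traj = small_system
        out = sc.center_on_selection(traj, "resid 138-140")
        idx = sc.select(out.topology, "resid 138-140")
        norms = np.linalg.norm(out.frames[:, idx, :].mean(axis=1), axis=1)
        assert norms.max() < 1e-9


class TestSuperpose:
    def _noisy_traj(self, rng, n_atoms=100, sigma=0.0, rotate=None):
        ref = rng.uniform(-20, 20, size=(n_atoms, 3))
        frame1 = ref.copy()
        if rotate is not None:
            frame1 = frame1 @ rotate.T
        if sigma:
            frame1 = frame1 + rng.normal(scale=sigma, size=frame1.shape)
        return _toy_traj([ref, frame1])

    def test_identical_frame_gives_identity(self):
        rng = np.random.default_rng(0)
        traj = self._noisy_traj(rng)
        _, results = sc.superpose_to_first_frame(traj, "all")
        np.testing.assert_allclose(results[1].rotation, np.eye(3), atol=1e-8)
        assert results[1].rmsd_after < 1e-9

    def test_pure_rotation_recovered(self):
        rng = np.random.default_rng(1)
        rot = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        traj = self._noisy_traj(rng, rotate=rot)
        out, results = sc.superpose_to_first_frame(traj, "all")
        assert results[1].rmsd_after < 1e-6
        np.testing.assert_allclose(out.frames[1], out.frames[0], atol=1e-6)

    def test_gaussian_noise_rmsd_matches_noise_model(self):
        # isotropic displacement noise of 3-D magnitude sigma = 0.1 Å on
        # 100 atoms: post-fit RMSD ~ sigma (the fit absorbs only 6-7 DOF)
        rmsds = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            traj = self._noisy_traj(rng, sigma=0.1 / np.sqrt(3.0))
            _, results = sc.superpose_to_first_frame(traj, "all")
            rmsds.append(results[1].rmsd_after)
        assert all(0.05 <= r <= 0.15 for r in rmsds)

    def test_rotation_is_proper_and_rmsd_never_worse(self, small_system):
        _, _, _, traj = small_system
        sub = sc.Trajectory(traj.topology, traj.frames[:5])
        _, results = sc.superpose_to_first_frame(sub, "protein")
        for r in results:
            np.testing.assert_allclose(r.rotation @ r.rotation.T, np.eye(3), atol=1e-8)
            assert abs(np.linalg.det(r.rotation) - 1.0) < 1e-8
            assert r.rmsd_after <= r.rmsd_before + 1e-9

    def test_collinear_fit_set_raises(self):
        coords = [[[float(i), 0, 0] for i in range(5)]] * 2
        with pytest.raises(AlignmentError):
            sc.superpose_to_first_frame(_toy_traj(coords), "all")

    def test_kabsch_matches_scipy_align_vectors(self):
        rng = np.random.default_rng(7)
        ref = rng.uniform(-10, 10, size=(30, 3))
        true_rot = Rotation.random(random_state=3).as_matrix()
        mobile = ref @ true_rot.T + rng.normal(scale=0.2, size=ref.shape)
        R, t = sc.kabsch(mobile, ref)
        est, _ = Rotation.align_vectors(
            ref - ref.mean(axis=0), mobile - mobile.mean(axis=0)
        )
        np.testing.assert_allclose(R, est.as_matrix(), atol=1e-8)


class TestStrip:
    def test_keep_all_is_identity(self, small_system):
        _, _, _, traj = small_system
        out = sc.strip(traj, "all")
        assert out.n_atoms == traj.n_atoms
        np.testing.assert_array_equal(out.frames, traj.frames)

    def test_substrate_strip_atom_count(self, small_system):
        # 20 molecules x 22 atoms + 20 x 24 atoms = 920 substrate atoms
        _, _, _, traj = small_system
        out = sc.strip(traj, "substrate")
        assert out.n_atoms == 920
        assert out.n_frames == traj.n_frames

    def test_strip_is_idempotent(self, small_system):
        _, _, _, traj = small_system
        once = sc.strip(traj, "substrate")
        twice = sc.strip(once, "substrate")
        np.testing.assert_array_equal(once.frames, twice.frames)

    def test_relative_atom_order_preserved(self, small_system):
        _, _, _, traj = small_system
        out = sc.strip(traj, "substrate")
        serials = [a.serial for a in out.topology.atoms]
        assert serials == sorted(serials)


class TestRigidMotionInvariants:
    def _pairwise(self, frame, idx):
        sub = frame[idx]
        return np.linalg.norm(sub[:, None, :] - sub[None, :, :], axis=-1)

    def test_center_and_superpose_preserve_distances(self, small_system):
        _, _, _, traj = small_system
        sub = sc.Trajectory(traj.topology, traj.frames[:5])
        idx = list(range(0, sub.n_atoms, 97))
        centered = sc.center_on_selection(sub, "resid 138-140")
        fitted, _ = sc.superpose_to_first_frame(centered, "protein")
        for k in range(sub.n_frames):
            before = self._pairwise(sub.frames[k], idx)
            after = self._pairwise(fitted.frames[k], idx)
            np.testing.assert_allclose(after, before, atol=1e-9)

    def test_superpose_is_a_projection(self, small_system):
        _, _, _, traj = small_system
        sub = sc.Trajectory(traj.topology, traj.frames[:4])
        once, _ = sc.superpose_to_first_frame(sub, "protein")
        twice, _ = sc.superpose_to_first_frame(once, "protein")
        np.testing.assert_allclose(twice.frames, once.frames, atol=1e-9)

    def test_strip_commutes_with_center(self, small_system):
        _, _, _, traj = small_system
        sub = sc.Trajectory(traj.topology, traj.frames[:4])
        a = sc.strip(sc.center_on_selection(sub, "substrate and type aha"), "substrate")
        b = sc.center_on_selection(sc.strip(sub, "substrate"), "substrate and type aha")
        np.testing.assert_allclose(a.frames, b.frames, atol=1e-9)
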