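"""Per-frame metric correctness against brute-force oracles and closed forms."""

import numpy as np
import pytest

import memgate as mg
from memgate.geometry import apply_transform, superpose_kabsch

from conftest import random_rotation


def _two_atom_traj(pos_a, pos_b, n_frames=5, box=None):
    atoms = [
        mg.AtomRecord(1, "CA", "ALA", 1, "A", "C", 1.7),
        mg.AtomRecord(2, "CB", "ALA", 2, "A", "C", 1.7),
    ]
    frames = np.tile(np.array([pos_a, pos_b], dtype=float), (n_frames, 1, 1))
    boxes = np.tile(box, (n_frames, 1)) if box is not None else None
    return mg.Trajectory(mg.Structure(atoms, frames[0]), frames, boxes=boxes)


class TestPairDistance:
    def test_three_four_five(self):
        traj = _two_atom_traj([0, 0, 0], [3, 4, 0])
        ts = mg.pair_distance_series(traj, "resid 1", "resid 2")
        np.testing.assert_allclose(ts.values, 5.0)

    def test_identical_atoms_zero(self):
        traj = _two_atom_traj([1, 1, 1], [1, 1, 1])
        ts = mg.pair_distance_series(traj, "resid 1", "resid 2")
        np.testing.assert_allclose(ts.values, 0.0)

    def test_brute_force_oracle(self, rng):
        atoms = [
            mg.AtomRecord(i + 1, "CA", "ALA", i + 1, "A", "C", 1.7) for i in range(2)
        ]
        frames = rng.normal(scale=15.0, size=(100, 2, 3))
        traj = mg.Trajectory(mg.Structure(atoms, frames[0]), frames)
        ts = mg.pair_distance_series(traj, "resid 1", "resid 2")
        expected = np.array(
            [np.sqrt(((f[1] - f[0]) ** 2).sum()) for f in frames]
        )
        np.testing.assert_allclose(ts.values, expected, atol=1e-9)

    def test_minimum_image_across_boundary(self):
        traj = _two_atom_traj([0.5, 0, 0], [9.5, 0, 0], box=[10.0, 10.0, 10.0])
        plain = mg.pair_distance_series(traj, "resid 1", "resid 2")
        wrapped = mg.pair_distance_series(
            traj, "resid 1", "resid 2", use_minimum_image=True
        )
        np.testing.assert_allclose(plain.values, 9.0)
        np.testing.assert_allclose(wrapped.values, 1.0)

    def test_multi_atom_selection_rejected(self, gating_traj):
        traj, _, _ = gating_traj
        with pytest.raises(ValueError, match="com_distance_series"):
            mg.pair_distance_series(traj, "resname HOH", "resid 372 and name CA")


class TestComDistance:
    def test_midpoint(self):
        atoms = [
            mg.AtomRecord(1, "C1", "GRP", 1, "A", "C", 1.7),
            mg.AtomRecord(2, "C2", "GRP", 1, "A", "C", 1.7),
            mg.AtomRecord(3, "C3", "GRP", 2, "A", "C", 1.7),
        ]
        frames = np.array([[[0, 0, 0], [2, 0, 0], [1, 5, 0]]], dtype=float)
        traj = mg.Trajectory(mg.Structure(atoms, frames[0]), frames)
        ts = mg.com_distance_series(traj, "resid 1", "resid 2")
        np.testing.assert_allclose(ts.values, 5.0)

    def test_single_atom_groups_match_pair_distance(self, rng):
        atoms = [
            mg.AtomRecord(i + 1, "CA", "ALA", i + 1, "A", "C", 1.7) for i in range(2)
        ]
        frames = rng.normal(size=(20, 2, 3))
        traj = mg.Trajectory(mg.Structure(atoms, frames[0]), frames)
        com = mg.com_distance_series(traj, "resid 1", "resid 2")
        pair = mg.pair_distance_series(traj, "resid 1", "resid 2")
        np.testing.assert_allclose(com.values, pair.values, atol=1e-12)

    def test_mass_weighted_oracle(self, rng):
        # CH4-like group: one carbon, four hydrogens
        elements = ["C", "H", "H", "H", "H"]
        atoms = [
            mg.AtomRecord(i + 1, e, "MET", 1, "A", e, 1.2) for i, e in enumerate(elements)
        ] + [mg.AtomRecord(6, "O", "REF", 2, "A", "O", 1.52)]
        frames = rng.normal(size=(10, 6, 3))
        traj = mg.Trajectory(mg.Structure(atoms, frames[0]), frames)
        ts = mg.com_distance_series(traj, "resid 1", "resid 2", weights="mass")
        from memgate._tables import mass_for

        w = np.array([mass_for(e) for e in elements])
        com = np.einsum("tnc,n->tc", frames[:, :5], w) / w.sum()
        expected = np.linalg.norm(frames[:, 5] - com, axis=1)
        np.testing.assert_allclose(ts.values, expected, atol=1e-9)

    def test_empty_group_error(self, gating_traj):
        traj, _, _ = gating_traj
        with pytest.raises(ValueError, match="non-empty"):
            mg.com_distance_series(traj, "chain Z", "resid 372")


class TestMovingSphereCount:
    def test_no_targets_all_zero(self):
        traj = _two_atom_traj([0, 0, 0], [2, 0, 0], n_frames=4)
        ts = mg.moving_sphere_count(
            traj, mg.SphereSpec("resid 1 2", 4.0), "resname HOH"
        )
        np.testing.assert_array_equal(ts.values, 0)

    def test_constructed_shell_placement(self):
        """7 waters at 3.9 Å and 5 at 4.1 Å from the centre, radius 4 → 7."""
        atoms = [
            mg.AtomRecord(1, "CA", "TRP", 335, "A", "C", 1.7),
            mg.AtomRecord(2, "CA", "PHE", 372, "A", "C", 1.7),
        ]
        coords = [[-1.0, 0, 0], [1.0, 0, 0]]  # centre of geometry = origin
        rng = np.random.default_rng(5)
        for i, r in enumerate([3.9] * 7 + [4.1] * 5):
            d = rng.normal(size=3)
            d /= np.linalg.norm(d)
            atoms.append(mg.AtomRecord(3 + i, "OW", "HOH", 500 + i, "W", "O", 1.52))
            coords.append((d * r).tolist())
        frames = np.tile(np.array(coords), (6, 1, 1))
        traj = mg.Trajectory(mg.Structure(atoms, frames[0]), frames)
        ts = mg.moving_sphere_count(
            traj, mg.SphereSpec("resid 335 372 and name CA", 4.0)
        )
        np.testing.assert_array_equal(ts.values, 7)

    def test_brute_force_recount_exact(self, gating_traj):
        traj, _, _ = gating_traj
        sphere = mg.SphereSpec("resid 335 372 and name CA", 4.0)
        ts = mg.moving_sphere_count(traj, sphere)
        cidx = traj.select(sphere.center_atoms)
        widx = traj.select("resname HOH and name OW")
        for t in range(0, traj.n_frames, 37):
            center = traj.frames[t, cidx].mean(axis=0)
            n = sum(
                np.linalg.norm(traj.frames[t, i] - center) <= 4.0 for i in widx
            )
            assert ts.values[t] == n

    def test_empty_center_is_error(self, gating_traj):
        traj, _, _ = gating_traj
        with pytest.raises(ValueError, match="centre"):
            mg.moving_sphere_count(traj, mg.SphereSpec("chain Z", 4.0))

    def test_boundary_closed(self):
        atoms = [
            mg.AtomRecord(1, "CA", "ALA", 1, "A", "C", 1.7),
            mg.AtomRecord(2, "OW", "HOH", 2, "W", "O", 1.52),
        ]
        frames = np.array([[[0, 0, 0], [4.0, 0, 0]]])
        traj = mg.Trajectory(mg.Structure(atoms, frames[0]), frames)
        ts = mg.moving_sphere_count(traj, mg.SphereSpec("resid 1", 4.0))
        assert ts.values[0] == 1


class TestPlaneAngle:
    SPEC = mg.PlaneAngleSpec(
        ("resid 1 and name T", "resid 1 and name H"),
        ("resid 2 and name P1", "resid 2 and name P2", "resid 2 and name P3"),
    )

    @staticmethod
    def _traj(vec_head, n_frames=3):
        names = ["T", "H", "P1", "P2", "P3"]
        resids = [1, 1, 2, 2, 2]
        atoms = [
            mg.AtomRecord(i + 1, n, "X", r, "A", "C", 1.7)
            for i, (n, r) in enumerate(zip(names, resids))
        ]
        coords = np.array(
            [[0, 0, 0], vec_head, [0, 0, 0], [1, 0, 0], [0, 1, 0]], dtype=float
        )
        frames = np.tile(coords, (n_frames, 1, 1))
        return mg.Trajectory(mg.Structure(atoms, frames[0]), frames)

    def test_in_plane_vector_zero(self):
        ts = mg.vector_plane_angle_series(self._traj([1, 1, 0]), self.SPEC)
        np.testing.assert_allclose(ts.values, 0.0, atol=1e-12)

    def test_parallel_to_normal_plus_ninety(self):
        ts = mg.vector_plane_angle_series(self._traj([0, 0, 2]), self.SPEC)
        np.testing.assert_allclose(ts.values, 90.0)

    def test_antiparallel_minus_ninety(self):
        ts = mg.vector_plane_angle_series(self._traj([0, 0, -2]), self.SPEC)
        np.testing.assert_allclose(ts.values, -90.0)

    def test_rigid_motion_invariance(self, rng):
        traj = self._traj([0.3, -1.2, 0.8], n_frames=8)
        ref = mg.vector_plane_angle_series(traj, self.SPEC)
        frames = traj.frames.copy()
        for t in range(frames.shape[0]):
            rot = random_rotation(rng)
            frames[t] = frames[t] @ rot.T + rng.normal(scale=50.0, size=3)
        moved = mg.Trajectory(traj.topology, frames)
        out = mg.vector_plane_angle_series(moved, self.SPEC)
        np.testing.assert_allclose(out.values, ref.values, atol=1e-9)

    def test_collinear_plane_names_frame(self):
        traj = self._traj([0, 0, 1], n_frames=2)
        traj.frames[1, 4] = [2, 0, 0]  # P3 collinear with P1-P2 at frame 1
        with pytest.raises(ValueError, match="frame 1"):
            mg.vector_plane_angle_series(traj, self.SPEC)


class TestRollingMean:
    def test_window_one_identity(self, rng):
        ts = mg.TimeSeries(np.arange(10.0), rng.normal(size=10))
        np.testing.assert_array_equal(mg.rolling_mean(ts, 1).values, ts.values)

    def test_constant_unchanged(self):
        ts = mg.TimeSeries(np.arange(9.0), np.full(9, 3.3))
        np.testing.assert_allclose(mg.rolling_mean(ts, 5).values, 3.3)

    def test_truncated_edges_hand_computed(self):
        ts = mg.TimeSeries(np.arange(5.0), [1, 2, 3, 4, 5])
        np.testing.assert_allclose(
            mg.rolling_mean(ts, 3).values, [1.5, 2, 3, 4, 4.5]
        )

    @pytest.mark.parametrize("window", [0, -3])
    def test_bad_window(self, window):
        ts = mg.TimeSeries(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError):
            mg.rolling_mean(ts, window)

    def test_window_longer_than_series(self):
        ts = mg.TimeSeries(np.arange(5.0), np.ones(5))
        with pytest.raises(ValueError, match="exceeds"):
            mg.rolling_mean(ts, 6)


class TestKabsch:
    def test_identity_on_self(self, rng):
        pts = rng.normal(size=(12, 3))
        rot, trans, rmsd = superpose_kabsch(pts, pts)
        np.testing.assert_allclose(rot, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(trans, 0.0, atol=1e-9)
        assert rmsd < 1e-9

    def test_recovers_known_transform(self, rng):
        pts = rng.normal(size=(25, 3))
        rot_true = random_rotation(rng)
        t_true = np.array([3.0, -7.0, 11.0])
        moved = pts @ rot_true.T + t_true
        rot, trans, rmsd = superpose_kabsch(pts, moved)
        np.testing.assert_allclose(rot, rot_true, atol=1e-9)
        np.testing.assert_allclose(trans, t_true, atol=1e-9)
        assert rmsd < 1e-9
        np.testing.assert_allclose(apply_transform(pts, rot, trans), moved, atol=1e-9)

    def test_reflection_yields_proper_rotation(self, rng):
        pts = rng.normal(size=(15, 3))
        mirrored = pts * np.array([-1.0, 1.0, 1.0])
        rot, _, _ = superpose_kabsch(pts, mirrored)
        assert np.linalg.det(rot) == pytest.approx(1.0, abs=1e-9)

    def test_too_few_or_degenerate_points(self, rng):
        with pytest.raises(ValueError):
            superpose_kabsch(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))
        line = np.outer(np.arange(5.0), [1.0, 0, 0])
        with pytest.raises(ValueError, match="degenerate"):
            superpose_kabsch(line, line)
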