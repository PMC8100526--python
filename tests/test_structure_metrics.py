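"""Superposition/RMSD, SASA, helix axes and distance metrics."""

import numpy as np
import pytest

from mechbond.structure_metrics import (
    atom_pair_distance,
    buried_sasa,
    ca_rmsd_series,
    centroid_distance,
    helix_axis,
    interhelix_angle,
    kabsch_superpose,
    shrake_rupley_sasa,
)
from mechbond.synthetic import BondSpec, gen_helix, gen_interface_trajectory
from mechbond.traj_io import Topology, Trajectory

from conftest import random_rigid_motion


def _sphere_trajectory(centers, element="C"):
    n = len(centers)
    top = Topology(
        [f"C{i}" for i in range(n)], [element] * n, ["UNK"] * n, list(range(1, n + 1)), ["A"] * n
    )
    return Trajectory(top, np.asarray(centers, dtype=float)[None])


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_superpose(pts, pts).rmsd == pytest.approx(0.0, abs=1e-12)

    def test_rigid_copy_recovered(self):
        rng = np.random.default_rng(1)
        pts = rng.normal(size=(20, 3))
        for _ in range(5):
            R, t = random_rigid_motion(rng)
            res = kabsch_superpose(pts @ R.T + t, pts)
            assert res.rmsd < 1e-6
            assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)

    def test_two_point_radial_displacement_closed_form(self):
        """Two of N points displaced radially by 1 Å with zero net
        translation/torque: optimal superposition is the identity and
        rmsd = sqrt(2/N)."""
        rng = np.random.default_rng(2)
        cloud = rng.normal(size=(18, 3))
        cloud -= cloud.mean(axis=0)
        a = np.array([5.0, 0.0, 0.0])
        ref = np.vstack([cloud, a, -a])
        mob = np.vstack([cloud, a + [1, 0, 0], -a - [1, 0, 0]])
        N = len(ref)
        assert kabsch_superpose(mob, ref).rmsd == pytest.approx(np.sqrt(2.0 / N), rel=1e-9)

    def test_count_mismatch_and_too_few(self):
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRmsdSeries:
    def test_static_trajectory_all_zero(self):
        traj, _ = gen_interface_trajectory([BondSpec(1.0)], n_frames=5, seed=0)
        series = ca_rmsd_series(traj, selection=traj.select("all"))
        np.testing.assert_allclose(series, 0.0, atol=1e-9)

    def test_first_frame_is_reference(self, toy_trajectory):
        traj, _ = toy_trajectory
        assert ca_rmsd_series(traj, reference_frame=0)[0] == pytest.approx(0.0, abs=1e-9)

    def test_rigid_motion_removed_by_superposition(self, toy_trajectory):
        traj, _ = toy_trajectory
        rng = np.random.default_rng(4)
        moved = traj.coords.copy()
        for i in range(1, traj.n_frames):
            R, t = random_rigid_motion(rng)
            moved[i] = moved[i] @ R.T + t
        m = Trajectory(traj.topology, moved)
        base = ca_rmsd_series(traj)
        drifted = ca_rmsd_series(m)
        np.testing.assert_allclose(drifted, base, atol=1e-6)

    def test_jittered_trajectory_matches_numpy_svd_oracle(self):
        """Per-frame superposed RMSD agrees with an independent Kabsch
        implementation written directly on numpy SVD."""
        rng = np.random.default_rng(7)
        base = rng.normal(scale=5.0, size=(30, 3))
        coords = base[None] + rng.normal(scale=0.3, size=(6, 30, 3))
        coords[0] = base
        top = Topology(
            ["CA"] * 30, ["C"] * 30, ["GLY"] * 30, list(range(1, 31)), ["A"] * 30
        )
        traj = Trajectory(top, coords)
        series = ca_rmsd_series(traj)

        def kabsch_rmsd(P, Q):
            P = P - P.mean(axis=0)
            Q = Q - Q.mean(axis=0)
            H = P.T @ Q
            U, S, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            D = np.diag([1.0, 1.0, d])
            R = Vt.T @ D @ U.T
            return np.sqrt(np.mean(np.sum((P @ R.T - Q) ** 2, axis=1)))

        expected = [kabsch_rmsd(coords[i], coords[0]) for i in range(6)]
        np.testing.assert_allclose(series, expected, atol=1e-9)

    def test_no_superpose_mode(self):
        traj, _ = gen_interface_trajectory([BondSpec(1.0)], n_frames=2, seed=0)
        shifted = traj.coords.copy()
        shifted[1] += [3.0, 0.0, 0.0]
        m = Trajectory(traj.topology, shifted)
        sel = m.select("all")
        raw = ca_rmsd_series(m, selection=sel, superpose=False)
        assert raw[1] == pytest.approx(3.0)
        assert ca_rmsd_series(m, selection=sel)[1] == pytest.approx(0.0, abs=1e-6)


class TestSasa:
    def test_isolated_sphere_closed_form(self):
        traj = _sphere_trajectory([[0.0, 0.0, 0.0]])
        res = shrake_rupley_sasa(traj.frame(0), n_points=960)
        exact = 4.0 * np.pi * (1.7 + 1.4) ** 2
        assert res.total == pytest.approx(exact, rel=0.01)

    def test_disjoint_spheres_additive(self):
        one = shrake_rupley_sasa(_sphere_trajectory([[0, 0, 0]]).frame(0)).total
        two = shrake_rupley_sasa(
            _sphere_trajectory([[0, 0, 0], [20.0, 0, 0]]).frame(0)
        ).total
        assert two == pytest.approx(2 * one, rel=1e-6)

    def test_two_overlapping_spheres_analytic(self):
        """Union of two equal spheres: each loses a cap of area 2πR(R−D/2)."""
        D = 2.0
        traj = _sphere_trajectory([[0, 0, 0], [D, 0, 0]])
        res = shrake_rupley_sasa(traj.frame(0), n_points=4000)
        R = 1.7 + 1.4
        exact = 2 * (4 * np.pi * R**2 - 2 * np.pi * R * (R - D / 2))
        assert res.total == pytest.approx(exact, rel=0.02)

    def test_burial_monotone_in_context(self):
        lone = shrake_rupley_sasa(_sphere_trajectory([[0, 0, 0]]).frame(0)).total
        pair = _sphere_trajectory([[0, 0, 0], [3.0, 0, 0]])
        sel_first = pair.select("resid 1")
        in_context = shrake_rupley_sasa(pair.frame(0), sel_first).total
        assert in_context <= lone + 1e-9

    def test_unknown_element_error_names_atom(self):
        traj = _sphere_trajectory([[0, 0, 0]], element="XX")
        with pytest.raises(ValueError, match="XX"):
            shrake_rupley_sasa(traj.frame(0))


class TestBuriedSasa:
    def test_separated_chains_zero(self):
        traj, _ = gen_interface_trajectory([BondSpec(1.0)], n_frames=1, seed=0)
        apart = traj.coords.copy()
        apart[0, 5:, 1] += 100.0  # receptor residue far away
        m = Trajectory(traj.topology, apart)
        b = buried_sasa(m.frame(0), m.select("chain A"), m.select("chain B"), n_points=240)
        assert b == pytest.approx(0.0, abs=1e-6)

    def test_symmetric_under_chain_swap(self, toy_trajectory):
        traj, _ = toy_trajectory
        f = traj.frame(0)
        a, b = traj.select("chain A"), traj.select("chain B")
        assert buried_sasa(f, a, b, n_points=240) == pytest.approx(
            buried_sasa(f, b, a, n_points=240)
        )

    def test_two_sphere_interface_analytic(self):
        D = 2.0
        traj = _sphere_trajectory([[0, 0, 0], [D, 0, 0]])
        a = traj.select("resid 1")
        b = traj.select("resid 2")
        got = buried_sasa(traj.frame(0), a, b, n_points=4000)
        R = 1.7 + 1.4
        exact = 2 * (2 * np.pi * R * (R - D / 2))  # both buried caps
        assert got == pytest.approx(exact, rel=0.02)

    def test_overlapping_selections_error(self, toy_trajectory):
        traj, _ = toy_trajectory
        with pytest.raises(ValueError):
            buried_sasa(traj.frame(0), traj.select("all"), traj.select("chain B"))

    def test_nonnegative(self, toy_trajectory):
        traj, _ = toy_trajectory
        for i in range(0, traj.n_frames, 10):
            assert (
                buried_sasa(
                    traj.frame(i), traj.select("chain A"), traj.select("chain B"),
                    n_points=120,
                )
                >= 0.0
            )


class TestHelixAxis:
    def test_ideal_helix_recovery(self):
        ca = gen_helix(25)
        ax = helix_axis(ca)
        angle = np.degrees(np.arccos(np.clip(ax.direction @ [0, 0, 1], -1, 1)))
        assert angle < 2.0

    def test_reversal_flips_sign(self):
        ca = gen_helix(25)
        fwd = helix_axis(ca).direction
        rev = helix_axis(ca[::-1]).direction
        assert fwd @ rev < -0.99

    def test_collinear_points_exact(self):
        pts = np.outer(np.arange(6, dtype=float), [1.0, 0.0, 0.0])
        d = helix_axis(pts).direction
        np.testing.assert_allclose(d, [1, 0, 0], atol=1e-12)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            helix_axis(np.zeros((3, 3)))

    def test_generation_equivariance(self):
        """Rotating the generated helix rotates the recovered axis."""
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("xyz", [0.3, -1.0, 2.0]).as_matrix()
        d0 = helix_axis(gen_helix(25)).direction
        d1 = helix_axis(gen_helix(25) @ R.T).direction
        np.testing.assert_allclose(d1, R @ d0, atol=1e-9)

    @pytest.mark.parametrize(
        "u, v, expected",
        [
            ([0, 0, 1], [0, 0, 1], 0.0),
            ([0, 0, 1], [1, 0, 0], 90.0),
            ([0, 0, 1], [0, 0, -1], 180.0),
        ],
    )
    def test_interhelix_angle(self, u, v, expected):
        from mechbond.structure_metrics import HelixAxis

        a = HelixAxis(np.zeros(3), np.asarray(u, dtype=float))
        b = HelixAxis(np.zeros(3), np.asarray(v, dtype=float))
        assert interhelix_angle(a, b) == pytest.approx(expected)


class TestDistances:
    def _two_atom_body(self, point):
        top = Topology(
            ["C1", "C2", "CA"], ["C", "C", "C"], ["UNK"] * 3, [1, 2, 3], ["A", "A", "B"]
        )
        coords = np.array([[-1.0, 0, 0], [1.0, 0, 0], point])[None]
        return Trajectory(top, coords)

    def test_centroid_distance_example(self):
        traj = self._two_atom_body([3.0, 0.0, 0.0])
        body = traj.select("chain A")
        assert centroid_distance(traj.frame(0), body, ("B", 3, "CA")) == pytest.approx(3.0)

    def test_translation_invariance(self):
        traj = self._two_atom_body([3.0, 0.0, 0.0])
        shifted = Trajectory(traj.topology, traj.coords + 17.0)
        body = shifted.select("chain A")
        assert centroid_distance(shifted.frame(0), body, ("B", 3, "CA")) == pytest.approx(3.0)

    def test_atom_at_centroid_zero(self):
        traj = self._two_atom_body([0.0, 0.0, 0.0])
        body = traj.select("chain A")
        assert centroid_distance(traj.frame(0), body, ("B", 3, "CA")) == pytest.approx(0.0)

    def test_missing_atom_error(self):
        traj = self._two_atom_body([0.0, 0.0, 0.0])
        with pytest.raises(KeyError):
            centroid_distance(traj.frame(0), traj.select("chain A"), ("B", 9, "CA"))

    def test_atom_pair_distance(self):
        traj = self._two_atom_body([1.0, 1.0, 0.0])
        f = traj.frame(0)
        assert atom_pair_distance(f, ("A", 1, "C1"), ("A", 2, "C2")) == pytest.approx(2.0)
        assert atom_pair_distance(f, ("A", 1, "C1"), ("A", 1, "C1")) == 0.0

    def test_pair_distance_rotation_invariant(self):
        rng = np.random.default_rng(5)
        traj = self._two_atom_body([1.0, 1.0, 0.0])
        R, t = random_rigid_motion(rng)
        moved = Trajectory(traj.topology, traj.coords @ R.T + t)
        assert atom_pair_distance(
            moved.frame(0), ("A", 1, "C1"), ("A", 2, "C2")
        ) == pytest.approx(2.0)
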