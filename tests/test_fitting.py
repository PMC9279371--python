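"""Rotation sampling, FFT translational search, match scoring, simplex."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from mcbuild.errors import FittingError
from mcbuild.fitting import (Pose, RotationSet, exhaustive_fit,
                             fft_translation_scores, generate_rotations,
                             match_score, rasterize_points, simplex_refine)
from mcbuild.grid import DensityGrid
from mcbuild.probfield import MainChainPointSet
from mcbuild.fixtures import make_random_walk

from conftest import random_rotation, rmsd, tiny_chain


def direct_translation_scores(A, B, theta):
    """Brute-force oracle for the circular shift correlation."""
    nx, ny, nz = A.shape
    S = np.zeros_like(A)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                shifted = np.roll(B, shift=(-i, -j, -k), axis=(0, 1, 2))
                S[i, j, k] = -theta * float((A * shifted).sum())
    return S


class TestGenerateRotations:
    def test_ninety_degree_set_contains_identity(self):
        rs = generate_rotations(90.0)
        assert any(np.allclose(m, np.eye(3), atol=1e-12) for m in rs.matrices)
        assert len(rs) < 100

    def test_matrices_orthonormal_proper(self):
        rs = generate_rotations(45.0)
        for m in rs.matrices:
            assert np.abs(m.T @ m - np.eye(3)).max() < 1e-10
            assert np.linalg.det(m) == pytest.approx(1.0, abs=1e-10)

    def test_no_duplicate_orientations(self):
        rs = generate_rotations(30.0)
        quats = Rotation.from_matrix(rs.matrices).as_quat()
        quats *= np.where(quats[:, [3]] < 0, -1, 1)
        dots = np.abs(quats @ quats.T)
        np.fill_diagonal(dots, 0.0)
        # largest off-diagonal |q1.q2| corresponds to > dedup tolerance
        assert np.arccos(np.clip(dots.max(), -1, 1)) * 2 > np.radians(0.5)

    def test_interval_must_divide_circle(self):
        with pytest.raises(ValueError):
            generate_rotations(50.0)
        with pytest.raises(ValueError):
            generate_rotations(0.0)


class TestRasterize:
    def test_point_on_voxel_with_weight(self, rp6):
        g = rasterize_points(np.array([[3.0, 3.0, 3.0]]), np.array([1.0]),
                             rp6, 1.5, np.zeros(3), (5, 5, 5))
        assert g.values[2, 2, 2] == pytest.approx(1.0)
        g5 = rasterize_points(np.array([[3.0, 3.0, 3.0]]), np.array([0.5]),
                              rp6, 1.5, np.zeros(3), (5, 5, 5))
        assert g5.values[2, 2, 2] == pytest.approx(0.5)

    def test_two_point_field_is_max_of_singles(self, rp6):
        pts = np.array([[2.0, 2.0, 2.0], [5.0, 4.0, 2.0]])
        w = np.array([0.8, 0.6])
        shape, origin = (7, 7, 7), np.zeros(3)
        g_both = rasterize_points(pts, w, rp6, 1.5, origin, shape)
        g_a = rasterize_points(pts[:1], w[:1], rp6, 1.5, origin, shape)
        g_b = rasterize_points(pts[1:], w[1:], rp6, 1.5, origin, shape)
        np.testing.assert_allclose(g_both.values,
                                   np.maximum(g_a.values, g_b.values),
                                   atol=1e-12)

    def test_point_outside_grid_rejected(self, rp6):
        with pytest.raises(FittingError):
            rasterize_points(np.array([[99.0, 0.0, 0.0]]), np.array([1.0]),
                             rp6, 1.5, np.zeros(3), (4, 4, 4))


class TestFFTScores:
    def _grid(self, values, spacing=1.5):
        return DensityGrid(values, np.full(3, spacing), np.zeros(3))

    def test_delta_correlation(self, rp6):
        A = np.zeros((4, 4, 4))
        A[1, 2, 3] = 1.0
        sv = fft_translation_scores(self._grid(A), self._grid(A.copy()), rp6)
        assert sv.S[0, 0, 0] == pytest.approx(-rp6.theta, rel=1e-12)
        rest = sv.S.copy()
        rest[0, 0, 0] = 0.0
        np.testing.assert_allclose(rest, 0.0, atol=1e-15)

    def test_matches_direct_triple_sum_on_random_grids(self, rp6):
        rng = np.random.default_rng(11)
        for shape in [(4, 4, 4), (5, 3, 4), (8, 8, 8)]:
            A = rng.random(shape)
            B = rng.random(shape)
            sv = fft_translation_scores(self._grid(A), self._grid(B), rp6)
            oracle = direct_translation_scores(A, B, rp6.theta)
            assert np.abs(sv.S - oracle).max() < 1e-9 * rp6.theta

    def test_zero_grid_scores_zero(self, rp6):
        A = self._grid(np.zeros((4, 4, 4)))
        B = self._grid(np.random.default_rng(0).random((4, 4, 4)))
        sv = fft_translation_scores(A, B, rp6)
        np.testing.assert_allclose(sv.S, 0.0, atol=1e-15)

    def test_shape_mismatch_rejected(self, rp6):
        with pytest.raises(FittingError):
            fft_translation_scores(self._grid(np.zeros((4, 4, 4))),
                                   self._grid(np.zeros((5, 4, 4))), rp6)


class TestMatchScore:
    def test_atom_on_unit_point_scores_minus_theta(self, rp6):
        Z = MainChainPointSet(np.zeros((1, 3)), np.ones(1))
        assert match_score(np.zeros((1, 3)), Z, rp6) == \
            pytest.approx(-rp6.theta, rel=1e-12)

    def test_distance_decay_at_r4(self, rp4):
        Z = MainChainPointSet(np.zeros((1, 3)), np.ones(1))
        s = match_score(np.array([[1.0, 0.0, 0.0]]), Z, rp4)
        assert s == pytest.approx(-rp4.theta * np.exp(-rp4.lam), rel=1e-12)
        assert s == pytest.approx(-0.730 * rp4.theta, abs=1e-3 * rp4.theta)

    def test_max_picks_strongest_weighted_point(self, rp6):
        Z = MainChainPointSet(np.array([[2.0, 0, 0], [-2.0, 0, 0]]),
                              np.array([0.9, 0.5]))
        s = match_score(np.zeros((1, 3)), Z, rp6)
        assert s == pytest.approx(-rp6.theta * 0.9 * np.exp(-rp6.lam * 4.0),
                                  rel=1e-12)

    def test_scores_nonpositive_and_zero_far_away(self, rp6, helix40_points):
        far = np.full((5, 3), 500.0)
        assert match_score(far, helix40_points, rp6) == 0.0
        near = helix40_points.points[:10]
        assert match_score(near, helix40_points, rp6) < 0.0

    def test_invariant_under_joint_rigid_motion(self, rp6):
        rng = np.random.default_rng(4)
        atoms = rng.normal(size=(12, 3)) * 3
        pts = rng.normal(size=(30, 3)) * 4
        prob = rng.uniform(0.2, 1.0, 30)
        s0 = match_score(atoms, MainChainPointSet(pts, prob), rp6)
        for seed in range(5):
            R = random_rotation(seed)
            t = rng.normal(size=3) * 10
            s = match_score(atoms @ R.T + t,
                            MainChainPointSet(pts @ R.T + t, prob), rp6)
            assert s == pytest.approx(s0, rel=1e-6)

    def test_empty_point_set_rejected(self, rp6):
        with pytest.raises((FittingError, ValueError)):
            match_score(np.zeros((1, 3)),
                        MainChainPointSet(np.empty((0, 3)), np.empty(0)), rp6)


class TestExhaustiveFit:
    def test_keep_contract(self, rp6, helix40_points, helix40, rots30):
        small = RotationSet(rots30.matrices[:40], 30.0)
        p1 = exhaustive_fit(helix40, helix40_points, small, rp6, keep=1)
        assert len(p1) == 1
        p10 = exhaustive_fit(helix40, helix40_points, small, rp6, keep=10)
        assert len(p10) == 10
        scores = [p.score for p in p10]
        assert scores == sorted(scores)

    def test_twin_motif_top_poses_land_on_distinct_copies(self, rp6):
        """Two disjoint copies of the same motif: the two best poses must
        occupy different copies."""
        from mcbuild.probfield import simulate_probability_map, \
            reduce_map_to_points
        motif = make_random_walk(20, seed=9)
        copy2 = motif.transformed(np.eye(3), np.array([30.0, 0.0, 0.0]))
        g = simulate_probability_map([motif, copy2], rp6, spacing=1.0)
        Z = reduce_map_to_points(g, rp6)
        rots = RotationSet(np.stack([np.eye(3)]
                                    + [random_rotation(i) for i in range(6)]),
                           45.0)
        poses = exhaustive_fit(motif, Z, rots, rp6, keep=4)
        centers = [p.apply(motif.main_chain_coords()).mean(axis=0)
                   for p in poses[:2]]
        sites = np.array([[10.0, 0.0, 0.0], [40.0, 0.0, 0.0]])
        labels = {int(np.linalg.norm(sites - c, axis=1).argmin())
                  for c in centers}
        assert labels == {0, 1}


class TestSimplexRefine:
    def _system(self, rp):
        Z = MainChainPointSet(np.array([[0.0, 0, 0], [3.8, 0, 0],
                                        [7.6, 0, 0]]), np.ones(3))
        chain = tiny_chain(Z.points.copy())
        return chain, Z

    def test_stationary_at_global_optimum(self, rp6):
        chain, Z = self._system(rp6)
        out = simplex_refine(Pose.identity(), chain, Z, rp6)
        assert out.score == pytest.approx(-3 * rp6.theta, rel=1e-9)
        np.testing.assert_allclose(out.apply(chain.main_chain_coords()),
                                   Z.points, atol=0.05)

    def test_displaced_start_strictly_improves(self, rp6):
        chain, Z = self._system(rp6)
        start = Pose(np.eye(3), np.array([1.0, 0.0, 0.0]))
        start.score = match_score(start.apply(chain.main_chain_coords()),
                                  Z, rp6)
        out = simplex_refine(start, chain, Z, rp6)
        assert out.score < start.score

    def test_never_worsens_over_random_starts(self, rp6):
        chain, Z = self._system(rp6)
        rng = np.random.default_rng(21)
        for _ in range(100):
            R = Rotation.from_rotvec(rng.normal(size=3) * 0.4).as_matrix()
            t = rng.normal(size=3) * 3.0
            start = Pose(R, t)
            s_in = match_score(start.apply(chain.main_chain_coords()), Z, rp6)
            out = simplex_refine(start, chain, Z, rp6)
            assert out.score <= s_in + 1e-15
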