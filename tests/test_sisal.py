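import itertools

import numpy as np
import pytest

from stsisal.sisal import (
    affine_project,
    pseudo_proportions,
    sisal_fit,
)

TRIANGLE = np.array([[0.0, 0.0], [1.0, 0.1], [0.4, 1.3]])


def _simplex_cloud(V, n, seed=1, include_vertices=True):
    rng = np.random.default_rng(seed)
    W = rng.dirichlet(np.ones(V.shape[0]), size=n)
    pts = W @ V
    if include_vertices:
        pts = np.vstack([V, pts])
    return pts


def _align_error(est, true):
    return min(np.abs(est[list(p)] - true).max()
               for p in itertools.permutations(range(true.shape[0])))


class TestAffineProject:
    def test_noiseless_round_trip(self):
        rng = np.random.default_rng(0)
        V3 = rng.random((3, 8))  # K=3 vertices in 8-dim ambient space
        pts = _simplex_cloud(V3, 50, seed=2)
        aff, proj = affine_project(pts, 3)
        lifted = aff.lift(proj)
        np.testing.assert_allclose(lifted, pts, atol=1e-8)

    def test_basis_orthonormal(self):
        rng = np.random.default_rng(1)
        pts = rng.random((40, 6))
        aff, _ = affine_project(pts, 4)
        np.testing.assert_allclose(aff.basis @ aff.basis.T, np.eye(3),
                                   atol=1e-10)

    def test_degenerate_cloud_raises(self):
        pts = np.ones((10, 5))
        with pytest.raises(ValueError, match="reduce K"):
            affine_project(pts, 2)

    def test_rank_deficiency_detected(self):
        # points on a line cannot support a K=3 projection
        t = np.linspace(0, 1, 20)[:, None]
        pts = t @ np.ones((1, 4))
        with pytest.raises(ValueError, match="rank"):
            affine_project(pts, 3)


class TestSisalFit:
    def test_recovers_vertices_from_noiseless_cloud(self):
        pts = _simplex_cloud(TRIANGLE, 197, seed=1)
        sv = sisal_fit(pts, 3, tau=100.0, seed=0)
        assert _align_error(sv.vertices_projected, TRIANGLE) < 1e-4

    def test_k2_vertices_are_extreme_points(self):
        rng = np.random.default_rng(3)
        pts = rng.random(60)[:, None]
        sv = sisal_fit(pts, 2, tau=100.0, seed=0)
        got = np.sort(sv.vertices_projected.ravel())
        np.testing.assert_allclose(got, [pts.min(), pts.max()], atol=1e-6)

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(4)
        W = rng.dirichlet(np.ones(3), size=300)
        pts = (0.8 * W + 0.2 / 3) @ TRIANGLE + rng.normal(0, 0.01, (300, 2))
        sv = sisal_fit(pts, 3, tau=1.0, seed=0)
        trace = np.array(sv.objective_trace)
        assert (np.diff(trace) <= 1e-9).all()

    def test_volume_not_expanded_on_noiseless_data(self):
        pts = _simplex_cloud(TRIANGLE, 100, seed=5)
        sv = sisal_fit(pts, 3, tau=100.0, seed=0)
        assert sv.volume <= sv.volume_init + 1e-9

    def test_hinge_zero_in_hard_constraint_limit(self):
        pts = _simplex_cloud(TRIANGLE, 100, seed=6)
        sv = sisal_fit(pts, 3, tau=1e4, seed=0)
        X = np.vstack([pts.T, np.ones((1, pts.shape[0]))])
        bary = sv.Q @ X
        assert bary.min() > -1e-6

    def test_matches_exhaustive_min_volume_search_small(self):
        # on <= 12 points with the vertices among them, the minimum-volume
        # enclosing triangle found by brute force is the generating one
        pts = _simplex_cloud(TRIANGLE, 9, seed=7)  # 3 vertices + 9 interior
        best, best_vol = None, np.inf
        for trio in itertools.combinations(range(len(pts)), 3):
            V = pts[list(trio)]
            E = V[1:] - V[0]
            vol = abs(np.linalg.det(E))
            if vol < 1e-12:
                continue
            A = np.vstack([V.T, np.ones(3)])
            B = np.vstack([pts.T, np.ones(len(pts))])
            bary = np.linalg.solve(A, B)
            if bary.min() >= -1e-9 and vol < best_vol:
                best, best_vol = V, vol
        assert best is not None
        assert _align_error(best, TRIANGLE) < 1e-12
        sv = sisal_fit(pts, 3, tau=100.0, seed=0)
        assert _align_error(sv.vertices_projected, best) < 1e-4

    def test_permutation_invariance_of_input_order(self):
        pts = _simplex_cloud(TRIANGLE, 80, seed=8)
        rng = np.random.default_rng(9)
        shuffled = pts[rng.permutation(len(pts))]
        a = sisal_fit(pts, 3, tau=100.0, seed=0)
        b = sisal_fit(shuffled, 3, tau=100.0, seed=0)
        assert _align_error(a.vertices_projected, b.vertices_projected) < 1e-6

    def test_seeded_determinism(self):
        pts = _simplex_cloud(TRIANGLE, 50, seed=10)
        a = sisal_fit(pts, 3, tau=1.0, seed=3)
        b = sisal_fit(pts, 3, tau=1.0, seed=3)
        np.testing.assert_array_equal(a.vertices_projected,
                                      b.vertices_projected)

    def test_too_few_points_raises(self):
        with pytest.raises(ValueError):
            sisal_fit(np.zeros((2, 2)), 3)


class TestPseudoProportions:
    def _fit(self):
        pts = _simplex_cloud(TRIANGLE, 100, seed=11)
        return sisal_fit(pts, 3, tau=100.0, seed=0)

    def test_vertex_maps_to_unit_coordinate(self):
        sv = self._fit()
        bp = pseudo_proportions(sv, sv.vertices_projected)
        np.testing.assert_allclose(bp, np.eye(3), atol=1e-8)

    def test_centroid_maps_to_uniform(self):
        sv = self._fit()
        centroid = sv.vertices_projected.mean(axis=0, keepdims=True)
        bp = pseudo_proportions(sv, centroid)
        np.testing.assert_allclose(bp, 1 / 3, atol=1e-8)

    def test_known_weights_recovered(self):
        sv = self._fit()
        rng = np.random.default_rng(12)
        W = rng.dirichlet(np.ones(3), size=25)          # (25, 3)
        pts = W @ sv.vertices_projected
        bp = pseudo_proportions(sv, pts)
        np.testing.assert_allclose(bp, W.T, atol=1e-8)

    def test_degenerate_simplex_raises(self):
        sv = self._fit()
        sv.vertices_projected = np.zeros_like(sv.vertices_projected)
        with pytest.raises(ValueError, match="degenerate"):
            pseudo_proportions(sv, np.zeros((1, 2)))
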