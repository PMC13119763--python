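"""Constrained RANSAC correspondence between IR and VIS marker sets."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from thermafoot.matching import (Affine2D, MatchConfig, NoMatchError,
                                 estimate_affine, monotonicity_check,
                                 neighbor_signature, oriented_area_sign,
                                 ransac_match, refine_and_finalize, shortlist)

SQUARE = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])


def _cloud(rng, n=8, span=100.0):
    """Well-separated random points (rejection-sampled minimum spacing)."""
    pts = []
    while len(pts) < n:
        p = rng.uniform(0, span, size=2)
        if all(np.linalg.norm(p - q) > span / 6 for q in pts):
            pts.append(p)
    return np.array(pts)


TRUE_AFFINE = Affine2D(linear=np.diag([2.85, 2.9]), translation=[40.0, -15.0])


class TestNeighborSignature:
    def test_square_corners_identical_signatures(self):
        sigs = neighbor_signature(SQUARE, k=2)
        np.testing.assert_allclose(sigs, 1.0)

    def test_scale_invariance(self, rng):
        pts = _cloud(rng)
        np.testing.assert_allclose(neighbor_signature(pts, 4),
                                   neighbor_signature(10.0 * pts, 4))

    def test_centre_point_distinct_from_corners(self):
        pts = np.vstack([SQUARE, [[0.5, 0.5]]])
        sigs = neighbor_signature(pts, k=3)
        # brute force: corner sees (0.707, 1, 1), centre sees (0.707 x 4)
        assert not np.allclose(sigs[4], sigs[0])
        np.testing.assert_allclose(sigs[4], 1.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            neighbor_signature(SQUARE[:3], k=3)


class TestShortlist:
    def test_identical_sets_rank_self_first(self, rng):
        pts = _cloud(rng)
        sigs = neighbor_signature(pts, 4)
        short = shortlist(sigs, sigs, m=3)
        np.testing.assert_array_equal(short[:, 0], np.arange(len(pts)))

    def test_m_larger_than_n_returns_all(self, rng):
        pts = _cloud(rng)
        sigs = neighbor_signature(pts, 4)
        assert shortlist(sigs, sigs, m=50).shape == (8, 8)

    def test_true_partner_in_top3_under_noise(self):
        """Noise at 1% of the inter-point scale keeps partners shortlisted."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = _cloud(rng)
            perm = rng.permutation(len(pts))
            vis = TRUE_AFFINE(pts[perm]) + rng.normal(0, 1.0, size=pts.shape)
            short = shortlist(neighbor_signature(pts, 4),
                              neighbor_signature(vis, 4), m=3)
            inv = np.argsort(perm)
            for i in range(len(pts)):
                assert inv[i] in short[i]


class TestOrientedArea:
    def test_reference_triplet_positive(self):
        assert oriented_area_sign([0, 0], [1, 0], [0, 1]) > 0

    def test_reflection_flips_sign(self, rng):
        for _ in range(10):
            tri = rng.uniform(0, 10, size=(3, 2))
            mirrored = tri * [-1.0, 1.0]
            a = oriented_area_sign(*tri)
            assert oriented_area_sign(*mirrored) == -a

    def test_collinear_is_zero(self):
        assert oriented_area_sign([0, 0], [1, 1], [2, 2]) == 0


class TestEstimateAffine:
    def test_identity_pairs(self, rng):
        pts = _cloud(rng)
        A = estimate_affine(pts, pts)
        np.testing.assert_allclose(A.linear, np.eye(2), atol=1e-12)
        np.testing.assert_allclose(A.translation, 0.0, atol=1e-10)

    def test_exact_recovery_of_known_transform(self, rng):
        th = np.radians(10.0)
        R = 1.3 * np.array([[np.cos(th), -np.sin(th)],
                            [np.sin(th), np.cos(th)]])
        truth = Affine2D(linear=R, translation=[40.0, -15.0])
        pts = _cloud(rng)
        A = estimate_affine(pts, truth(pts))
        np.testing.assert_allclose(A.linear, truth.linear, atol=1e-9)
        np.testing.assert_allclose(A.translation, truth.translation,
                                   atol=1e-8)

    def test_noisy_residual_tracks_dof_corrected_sigma(self):
        """Per-coordinate residual RMS ~ sigma * sqrt(1 - p/(2n)), where the
        affine's p=6 parameters absorb part of the 2n noisy observations."""
        sigma, n, p = 0.3, 6, 6
        expected = sigma * np.sqrt(1 - p / (2 * n))
        rmss = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            pts = _cloud(rng, n=n)
            vis = TRUE_AFFINE(pts) + rng.normal(0, sigma, size=pts.shape)
            A = estimate_affine(pts, vis)
            rmss.append(np.sqrt(np.mean((A(pts) - vis) ** 2)))
        assert np.sqrt(np.mean(np.square(rmss))) == pytest.approx(expected,
                                                                  rel=0.1)

    def test_collinear_rejected(self):
        line = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        with pytest.raises(ValueError):
            estimate_affine(line, line)

    def test_rotation_and_anisotropy_descriptors(self):
        th = np.radians(7.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        A = Affine2D(linear=R @ np.diag([3.0, 2.0]), translation=[0, 0])
        assert A.rotation_deg == pytest.approx(7.0, abs=1e-9)
        assert A.anisotropy == pytest.approx(1.5, rel=1e-9)


class TestMonotonicity:
    def test_order_preserving_is_perfect(self, rng):
        pts = _cloud(rng)
        pairs = [(i, i) for i in range(len(pts))]
        rx, ry, ok = monotonicity_check(pairs, pts, TRUE_AFFINE(pts), 0.8)
        assert (rx, ry, ok) == (1.0, 1.0, True)

    def test_single_swap_matches_rank_formula(self):
        # 8 collinear-x points with positions 0..7; swap partners of 3 and 4
        ir = np.column_stack([np.arange(8.0), np.zeros(8)])
        vis = ir.copy()
        pairs = [(i, i) for i in range(8)]
        pairs[3], pairs[4] = (3, 4), (4, 3)
        jj = [j for _, j in pairs]
        expected = spearmanr(np.arange(8), np.array(jj)).statistic
        # brute-force Spearman for a permutation: 1 - 6 sum d^2 / (n(n^2-1))
        d2 = sum((i - j) ** 2 for i, j in pairs)
        assert expected == pytest.approx(1 - 6 * d2 / (8 * 63))
        rx, _ry, _ok = monotonicity_check(pairs, ir, vis, 0.99)
        assert rx == pytest.approx(expected)
        assert rx < 1.0

    def test_reversed_order_fails(self):
        ir = np.column_stack([np.arange(8.0), np.arange(8.0)])
        vis = ir[::-1].copy()
        pairs = [(i, i) for i in range(8)]
        rx, ry, ok = monotonicity_check(pairs, ir, vis, 0.8)
        assert rx == -1.0 and ry == -1.0 and not ok


class TestRansacMatch:
    def test_identical_sets_full_identity_match(self, rng):
        pts = _cloud(rng)
        corr = ransac_match(pts, pts, seed=0)
        assert sorted(corr.pairs) == [(i, i) for i in range(len(pts))]
        np.testing.assert_allclose(corr.transform.linear, np.eye(2),
                                   atol=1e-9)
        assert corr.rho_x == corr.rho_y == 1.0
        assert np.all(corr.residuals < 1e-9)

    def test_mirrored_sets_rejected(self):
        """A left-right flipped point set admits no proper correspondence."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            pts = _cloud(rng)
            mirrored = TRUE_AFFINE(pts) * [-1.0, 1.0]
            with pytest.raises(NoMatchError) as exc:
                ransac_match(pts, mirrored, seed=seed)
            d = exc.value.diagnostics
            assert d.get("orientation", 0) + d.get("determinant", 0) \
                + d.get("geometry", 0) + d.get("too_few_inliers", 0) > 0

    def test_spurious_points_true_pairs_recovered(self):
        """8 IR + 10 VIS (2 spurious), known affine, 0.3 px noise: perfect
        recall and precision over 50 seeds."""
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ir = _cloud(rng, n=8)
            perm = rng.permutation(8)
            vis_true = TRUE_AFFINE(ir[perm])
            spurious = rng.uniform(vis_true.min(0) - 30, vis_true.max(0) + 30,
                                   size=(2, 2))
            vis = np.vstack([vis_true, spurious])
            order = rng.permutation(10)
            vis = vis[order] + rng.normal(0, 0.3, size=(10, 2))
            # expected pairing: ir index perm[k] <-> vis position of k
            where = np.argsort(order)
            expected = sorted((int(perm[k]), int(where[k])) for k in range(8))
            corr = ransac_match(ir, vis, seed=seed)
            assert sorted(corr.pairs) == expected

    def test_deterministic_given_seed(self, rng):
        ir = _cloud(rng)
        vis = TRUE_AFFINE(ir) + 0.2
        a = ransac_match(ir, vis, seed=7)
        b = ransac_match(ir, vis, seed=7)
        assert a.pairs == b.pairs
        np.testing.assert_array_equal(a.transform.as_matrix(),
                                      b.transform.as_matrix())

    def test_accepted_transform_proper_and_monotone(self, rng):
        ir = _cloud(rng)
        vis = TRUE_AFFINE(ir) + rng.normal(0, 0.3, size=ir.shape)
        corr = ransac_match(ir, vis, seed=3)
        assert corr.transform.det > 0
        cfg = MatchConfig()
        _rx, _ry, ok = monotonicity_check(corr.pairs, ir, vis,
                                          cfg.rho_min_strict)
        assert ok

    def test_too_few_points_is_no_match(self):
        with pytest.raises(NoMatchError):
            ransac_match(SQUARE[:2], SQUARE, seed=0)

    def test_greedy_fallback_agrees_on_clean_data(self, rng):
        ir = _cloud(rng)
        vis = TRUE_AFFINE(ir)
        a = ransac_match(ir, vis, seed=5)
        b = ransac_match(ir, vis, seed=5, greedy=True)
        assert sorted(a.pairs) == sorted(b.pairs)


class TestRefinement:
    def test_noiseless_fixture_unchanged(self, rng):
        ir = _cloud(rng)
        vis = TRUE_AFFINE(ir)
        pairs = [(i, i) for i in range(len(ir))]
        out = refine_and_finalize(pairs, ir, vis)
        assert sorted(out.pairs) == pairs
        assert np.all(out.residuals < 1e-9)

    def test_refinement_does_not_increase_residuals(self):
        cfg = MatchConfig()
        for seed in range(20):
            rng = np.random.default_rng(seed)
            ir = _cloud(rng)
            vis = TRUE_AFFINE(ir) + rng.normal(0, 0.5, size=ir.shape)
            corr = ransac_match(ir, vis, cfg, seed=seed)
            again = refine_and_finalize(corr.pairs, ir, vis, cfg)
            assert np.sqrt(np.mean(again.residuals ** 2)) <= \
                np.sqrt(np.mean(corr.residuals ** 2)) + 1e-9

    def test_second_pass_is_fixed_point(self, rng):
        ir = _cloud(rng)
        vis = TRUE_AFFINE(ir) + rng.normal(0, 0.3, size=ir.shape)
        first = refine_and_finalize([(i, i) for i in range(len(ir))], ir, vis)
        second = refine_and_finalize(first.pairs, ir, vis)
        assert sorted(first.pairs) == sorted(second.pairs)

    def test_inlier_collapse_is_no_match(self):
        ir = np.array([[0, 0], [10, 0], [0, 10], [10, 10.0]])
        vis = np.array([[0, 0], [500, 0], [0, 500], [900, 900.0]])
        with pytest.raises(NoMatchError):
            refine_and_finalize([(0, 0), (1, 1), (2, 2), (3, 3)], ir, vis)


class TestCorrespondenceSet:
    def test_duplicate_indices_rejected(self):
        from thermafoot.matching import CorrespondenceSet
        with pytest.raises(ValueError):
            CorrespondenceSet(pairs=[(0, 1), (0, 2)],
                              transform=TRUE_AFFINE,
                              residuals=np.zeros(2), rho_x=1.0, rho_y=1.0)
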