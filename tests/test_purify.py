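"""Ratio screening, cross-check, RANSAC and binomial match verification."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from endostitch.geometry import Homography33, apply_homography, solve_dlt
from endostitch.purify import (
    MatchCandidate,
    RansacConfig,
    VerificationParams,
    cross_validate,
    inlier_threshold,
    ransac_homography,
    ransac_iterations,
    ratio_filter,
    verify_image_match,
)
from endostitch.synthetic import PlantedMatchSpec, generate_matches


def cand(p, q, d1, d2):
    return MatchCandidate(p=p, q=q, d1=d1, d2=d2)


class TestRatioFilter:
    def test_clear_match_below_065_kept(self):
        assert ratio_filter([cand(0, 1, 0.3, 0.6)]) == [cand(0, 1, 0.3, 0.6)]

    def test_ambiguous_equal_distances_rejected(self):
        assert ratio_filter([cand(0, 1, 0.5, 0.5)]) == []

    def test_threshold_is_strict(self):
        exactly = cand(0, 1, 0.65, 1.0)
        assert ratio_filter([exactly], 0.65) == []

    def test_planted_ratios_counted_by_enumeration(self, rng):
        ratios = rng.uniform(0.3, 1.0, size=20)
        pairs = [cand(i, i, r * 0.5, 0.5) for i, r in enumerate(ratios)]
        kept = ratio_filter(pairs, 0.65)
        assert len(kept) == int((ratios < 0.65).sum())

    def test_degenerate_zero_second_distance_dropped(self):
        assert ratio_filter([cand(0, 1, 0.0, 0.0)]) == []

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_monotone_in_threshold(self, seed):
        g = np.random.default_rng(seed)
        pairs = [cand(i, i, float(g.uniform(0, 1)), 1.0) for i in range(30)]
        lo = {(c.p, c.q) for c in ratio_filter(pairs, 0.4)}
        hi = {(c.p, c.q) for c in ratio_filter(pairs, 0.8)}
        assert lo <= hi


class TestCrossValidate:
    def test_simple_intersection(self):
        A = [cand(1, 7, 0.1, 0.5), cand(2, 9, 0.1, 0.5)]
        B = [cand(7, 1, 0.1, 0.5)]
        assert [(c.p, c.q) for c in cross_validate(A, B)] == [(1, 7)]

    def test_empty_forward_set(self):
        assert cross_validate([], [cand(1, 2, 0.1, 0.5)]) == []

    def test_random_sets_match_double_loop_oracle(self, rng):
        A = [cand(int(p), int(q), 0.1, 0.5)
             for p, q in rng.integers(0, 50, size=(40, 2))]
        B = [cand(int(p), int(q), 0.1, 0.5)
             for p, q in rng.integers(0, 50, size=(40, 2))]
        got = [(c.p, c.q) for c in cross_validate(A, B)]
        want = []
        for a in A:
            for b in B:
                if a.p == b.q and a.q == b.p:
                    want.append((a.p, a.q))
                    break
        assert got == want

    def test_result_is_subset_of_A_in_A_order(self, rng):
        A = [cand(i, i + 1, 0.1, 0.5) for i in range(20)]
        B = [cand(i + 1, i, 0.1, 0.5) for i in range(20, 0, -2)]
        C = cross_validate(A, B)
        pos = [A.index(c) for c in C]
        assert pos == sorted(pos)
        assert set(C) <= set(A)


class TestRansacIterations:
    def test_all_inliers_needs_one_sample(self):
        assert ransac_iterations(0.99, 1.0) == 1

    def test_half_inliers_gives_72_samples(self):
        # ceil(log 0.01 / log(1 - 0.5^4)) — the standard sampling-count formula
        assert ransac_iterations(0.99, 0.5, 4) == 72

    def test_against_closed_form(self):
        for w in (0.3, 0.6, 0.9):
            want = math.ceil(math.log(0.01) / math.log(1 - w**4))
            assert ransac_iterations(0.99, w, 4) == want

    def test_non_increasing_in_inlier_fraction(self):
        ns = [ransac_iterations(0.99, w) for w in np.linspace(0.1, 1.0, 50)]
        assert all(a >= b for a, b in zip(ns, ns[1:]))

    def test_invalid_arguments_raise(self):
        with pytest.raises(ValueError):
            ransac_iterations(1.0, 0.5)
        with pytest.raises(ValueError):
            ransac_iterations(0.99, 0.0)


class TestInlierThreshold:
    def test_chi2_99_quantile_at_unit_sigma(self):
        t2 = inlier_threshold(RansacConfig(significance=0.01, sigma_noise=1.0))
        assert t2 == pytest.approx(9.210, abs=1e-3)

    def test_chi2_95_quantile(self):
        t2 = inlier_threshold(RansacConfig(significance=0.05, sigma_noise=1.0))
        assert t2 == pytest.approx(5.991, abs=1e-3)

    def test_matches_numerical_integration_of_chi2_density(self):
        """Independent oracle: invert the chi2_2 CDF by quadrature + bisection."""
        def cdf(x):
            val, _ = integrate.quad(lambda u: stats.chi2.pdf(u, 2), 0, x)
            return val

        lo, hi = 0.0, 50.0
        for _ in range(60):
            mid = (lo + hi) / 2
            if cdf(mid) < 0.99:
                lo = mid
            else:
                hi = mid
        t2 = inlier_threshold(RansacConfig(significance=0.01, sigma_noise=1.0))
        assert t2 == pytest.approx((lo + hi) / 2, abs=1e-6)

    def test_quadratic_in_sigma(self):
        base = inlier_threshold(RansacConfig(sigma_noise=1.0))
        assert inlier_threshold(RansacConfig(sigma_noise=2.0)) == pytest.approx(4 * base)


def planted(seed, n_in, n_out, sigma=1.0, near_miss=None):
    kw = {} if near_miss is None else {"near_miss_fraction": near_miss}
    return generate_matches(
        PlantedMatchSpec(n_inliers=n_in, n_outliers=n_out, sigma=sigma, seed=seed, **kw)
    )


class TestRansacHomography:
    def test_noiseless_set_recovers_ground_truth(self):
        pm = planted(0, 30, 0, sigma=1e-9)
        res = ransac_homography(pm.src, pm.dst, RansacConfig(seed=1))
        assert res.succeeded and res.n_inliers == 30
        corners = np.array([[0.0, 0.0], [400, 0], [400, 300], [0, 300]])
        np.testing.assert_allclose(
            apply_homography(res.H, corners),
            apply_homography(pm.H_true, corners),
            atol=1e-6,
        )

    def test_zero_outliers_equals_direct_least_squares(self):
        pm = planted(3, 25, 0, sigma=1e-9)
        res = ransac_homography(pm.src, pm.dst, RansacConfig(seed=2))
        H_ls = solve_dlt(pm.src, pm.dst)
        np.testing.assert_allclose(res.H.matrix, H_ls.matrix, atol=1e-9)

    def test_planted_contamination_recovered_over_seeds(self):
        """>= 95% of planted inliers kept, few outliers admitted (median)."""
        recovered, admitted = [], []
        for seed in range(20):
            # independent uniform outliers only: the cleanest contamination model
            pm = planted(seed, 100, 100, sigma=1.0, near_miss=0.0)
            res = ransac_homography(pm.src, pm.dst, RansacConfig(seed=seed))
            assert res.succeeded
            recovered.append((res.inlier_mask & pm.labels).sum())
            admitted.append((res.inlier_mask & ~pm.labels).sum())
        assert np.median(recovered) >= 95
        assert np.median(admitted) <= 5

    def test_seed_stability_of_inlier_counts(self):
        pm = planted(7, 120, 80)
        counts = [
            ransac_homography(pm.src, pm.dst, RansacConfig(seed=s)).n_inliers
            for s in (0, 1)
        ]
        assert abs(counts[0] - counts[1]) <= 3

    def test_too_few_pairs_raises(self):
        with pytest.raises(ValueError, match="[Ii]nsufficient"):
            ransac_homography(np.zeros((3, 2)), np.zeros((3, 2)))

    def test_hopeless_data_flags_failure(self, rng):
        src = rng.uniform(0, 100, (3, 2)).repeat(2, axis=0)[:5]
        src = np.vstack([src, src[:1]])  # heavy duplication, no valid model
        dst = rng.uniform(0, 100, (6, 2))
        res = ransac_homography(src, dst, RansacConfig(seed=0, max_iters=50))
        assert not res.succeeded or res.n_inliers < 6


class TestVerifyImageMatch:
    def test_empty_match_rejected(self):
        assert verify_image_match(0, 0).accepted is False

    def test_nf_100_accept_boundary_at_39(self):
        # threshold 8.0 + 0.3 * 100 = 38, strict inequality
        assert verify_image_match(100, 38).accepted is False
        assert verify_image_match(100, 39).accepted is True

    def test_monotone_in_inlier_count(self):
        decisions = [verify_image_match(100, ni).accepted for ni in range(101)]
        assert decisions == sorted(decisions)

    def test_posterior_diagnostic_increases_with_inliers(self):
        lo = verify_image_match(50, 5).posterior
        hi = verify_image_match(50, 40).posterior
        assert hi > lo
        assert 0.0 <= lo <= 1.0 and 0.0 <= hi <= 1.0

    def test_invalid_counts_raise(self):
        with pytest.raises(ValueError):
            verify_image_match(10, 11)
        with pytest.raises(ValueError):
            VerificationParams(p1=0.1, p0=0.6)


class TestCascadeOrdering:
    def test_purification_never_invents_pairs_and_c_subset_a(self):
        pm = planted(11, 60, 40)
        A = ratio_filter([cand(i, i, pm.d1[i], pm.d2[i]) for i in range(len(pm))])
        B = ratio_filter(
            [cand(i, i, pm.d1[i], pm.d2[i]) for i in range(len(pm)) if pm.mutual[i]]
        )
        C = cross_validate(A, B)
        assert {(c.p, c.q) for c in C} <= {(c.p, c.q) for c in A}

    def test_before_ransac_improved_precision_ordering(self):
        """Reproduces the qualitative three-column pattern on planted sets."""
        from endostitch.bench import run_benchmark

        rows = run_benchmark(n_seeds=10, base_seed=100)
        before = np.median([r.before.precision for r in rows])
        ronly = np.median([r.ransac_only.precision for r in rows])
        improved = np.median([r.improved.precision for r in rows])
        assert before < ronly < improved
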