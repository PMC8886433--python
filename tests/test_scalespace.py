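"""Scale-space construction, extremum detection, refinement, edge rejection."""

import numpy as np
import pytest

from endostitch import scalespace
from endostitch.scalespace import (
    CandidatePoint,
    DogStack,
    Keypoint,
    build_scale_space,
    detect_extrema,
    detect_keypoints,
    edge_response_filter,
    refine_keypoint,
)


def gaussian_blob(size=97, std=4.0, amplitude=1.0):
    """Bright blob centred on an integer pixel (odd size avoids plateau ties)."""
    yy, xx = np.mgrid[0:size, 0:size]
    c = size // 2
    return amplitude * np.exp(-((yy - c) ** 2 + (xx - c) ** 2) / (2 * std**2))


def make_dog(arrays, sigma0=1.6, intervals=3):
    """DogStack from a single handcrafted octave (test scaffolding)."""
    k = 2.0 ** (1.0 / intervals)
    n = arrays.shape[0] + 1
    return DogStack(
        octaves=[np.asarray(arrays, dtype=float)],
        sigmas=sigma0 * k ** np.arange(n),
        sigma0=sigma0,
        k=k,
        intervals=intervals,
    )


class TestBuildScaleSpace:
    def test_constant_image_gives_zero_dog_everywhere(self):
        ss, dog = build_scale_space(np.full((32, 32), 0.5))
        for D in dog.octaves:
            assert np.abs(D).max() == 0.0
        assert detect_extrema(dog) == []

    def test_layer_counts_for_three_intervals(self):
        ss, dog = build_scale_space(np.zeros((64, 64)), intervals=3)
        for G, D in zip(ss.octaves, dog.octaves):
            assert G.shape[0] == 6  # intervals + 3
            assert D.shape[0] == 5

    def test_sigmas_increase_by_k_and_octaves_downsample_by_two(self):
        ss, _ = build_scale_space(np.zeros((64, 64)), intervals=3)
        ratios = ss.sigmas[1:] / ss.sigmas[:-1]
        np.testing.assert_allclose(ratios, 2 ** (1 / 3))
        for a, b in zip(ss.octaves, ss.octaves[1:]):
            assert b.shape[1] == (a.shape[1] + 1) // 2

    def test_blob_response_peaks_at_matching_scale(self):
        """DoG response across layers is maximal where sigma ~ blob size.

        Brute-force scan over all layers of the centre-pixel response; the
        winning absolute scale must be the closest available to the blob std
        (scale-selection property of the scale-normalised Laplacian).
        """
        std = 4.0
        img = gaussian_blob(97, std)
        ss, dog = build_scale_space(img, octaves=2)
        best, best_sigma = -np.inf, None
        sigmas_seen = []
        for o, D in enumerate(dog.octaves):
            c = 97 // 2 // 2**o
            for layer in range(D.shape[0]):
                sig = ss.sigma_of(o, layer + 0.5)  # DoG layer sits between blurs
                sigmas_seen.append(sig)
                resp = abs(D[layer, c, c])
                if resp > best:
                    best, best_sigma = resp, sig
        closest = min(sigmas_seen, key=lambda s: abs(s - std))
        assert best_sigma == pytest.approx(closest)

    def test_dog_approximates_scale_normalised_log(self):
        """D ~ (k-1) sigma^2 lap(G)*I within 5% at the blob-centre peak."""
        from scipy import ndimage

        img = gaussian_blob(97, 5.0)
        # assumed_blur=0 so layer scales are exact for the analytic oracle
        ss, dog = build_scale_space(img, octaves=1, assumed_blur=0.0)
        c = 97 // 2
        for layer in range(1, 3):
            sig = float(ss.sigmas[layer])
            dog_resp = dog.octaves[0][layer, c, c]
            log_img = sig**2 * ndimage.gaussian_laplace(img, sig, mode="reflect")
            pred = (ss.k - 1.0) * log_img[c, c]
            assert dog_resp == pytest.approx(pred, rel=0.05)

    def test_too_many_octaves_raises_naming_feasible_count(self):
        with pytest.raises(ValueError, match="at most"):
            build_scale_space(np.zeros((32, 32)), octaves=10)

    def test_too_small_image_raises(self):
        with pytest.raises(ValueError, match="too small"):
            build_scale_space(np.zeros((8, 8)))

    def test_intensity_range_validated(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            build_scale_space(np.full((32, 32), 3.0))


class TestDetectExtrema:
    def test_single_impulse_detected_exactly_once(self):
        D = np.zeros((5, 16, 16))
        D[2, 7, 9] = 1.0
        cands = detect_extrema(make_dog(D))
        assert cands == [CandidatePoint(0, 2, 7, 9)]

    def test_negative_impulse_is_a_minimum(self):
        D = np.zeros((5, 16, 16))
        D[1, 5, 5] = -1.0
        assert detect_extrema(make_dog(D)) == [CandidatePoint(0, 1, 5, 5)]

    def test_plateau_of_equal_samples_not_reported(self):
        D = np.zeros((5, 16, 16))
        D[2, 7, 9] = D[2, 7, 10] = 1.0  # strict comparison must fail for both
        assert detect_extrema(make_dog(D)) == []

    def test_border_and_terminal_layers_excluded(self):
        D = np.zeros((3, 16, 16))
        D[0, 8, 8] = 1.0  # first layer
        D[2, 8, 8] = 1.0  # last layer
        D[1, 0, 5] = 1.0  # border row
        D[1, 5, 15] = 1.0  # border col
        assert detect_extrema(make_dog(D)) == []

    def test_every_26_neighbourhood_checked_exhaustively(self, rng):
        """Against a brute-force triple loop on a small random stack."""
        D = rng.normal(size=(4, 12, 12))
        got = {(c.layer, c.row, c.col) for c in detect_extrema(make_dog(D))}
        want = set()
        for l in range(1, 3):
            for r in range(1, 11):
                for c in range(1, 11):
                    nb = D[l - 1 : l + 2, r - 1 : r + 2, c - 1 : c + 2].ravel()
                    centre = D[l, r, c]
                    others = np.delete(nb, 13)
                    if centre > others.max() or centre < others.min():
                        want.add((l, r, c))
        assert got == want


def quadratic_octave(peak_offset, peak_value=0.1, curv=(0.02, 0.03, 0.015)):
    """Separable concave quadratic with analytic maximum at centre+offset."""
    shape = (5, 17, 17)
    l0, r0, c0 = 2 + peak_offset[2], 8 + peak_offset[1], 8 + peak_offset[0]
    ll, rr, cc = np.mgrid[0:5, 0:17, 0:17].astype(float)
    ax, ay, als = curv
    return (
        peak_value
        - ax * (cc - c0) ** 2
        - ay * (rr - r0) ** 2
        - als * (ll - l0) ** 2
    )


class TestRefineKeypoint:
    def test_peak_on_sample_gives_zero_offset(self):
        D = quadratic_octave((0.0, 0.0, 0.0), peak_value=0.1)
        kp = refine_keypoint(CandidatePoint(0, 2, 8, 8), make_dog(D))
        assert kp is not None
        np.testing.assert_allclose(kp.offset, 0.0, atol=1e-12)
        assert kp.contrast == pytest.approx(0.1)

    def test_recovers_analytic_subsample_offset(self):
        off = (0.3, -0.2, 0.1)
        D = quadratic_octave(off)
        kp = refine_keypoint(CandidatePoint(0, 2, 8, 8), make_dog(D))
        assert kp is not None
        np.testing.assert_allclose(kp.offset, off, atol=1e-6)
        assert kp.x == pytest.approx(8 + off[0], abs=1e-6)
        assert kp.y == pytest.approx(8 + off[1], abs=1e-6)

    def test_low_contrast_rejected_at_003(self):
        D = quadratic_octave((0.0, 0.0, 0.0), peak_value=0.02)
        assert refine_keypoint(CandidatePoint(0, 2, 8, 8), make_dog(D), 0.03) is None
        # and kept just above the threshold
        D = quadratic_octave((0.0, 0.0, 0.0), peak_value=0.04)
        assert refine_keypoint(CandidatePoint(0, 2, 8, 8), make_dog(D), 0.03) is not None

    def test_refinement_is_idempotent(self):
        D = quadratic_octave((0.3, -0.2, 0.1))
        dog = make_dog(D)
        kp1 = refine_keypoint(CandidatePoint(0, 2, 8, 8), dog)
        # re-run from the sample the first refinement converged on
        kp2 = refine_keypoint(CandidatePoint(0, kp1.layer, round(kp1.y), round(kp1.x)), dog)
        assert abs(kp1.x - kp2.x) < 1e-9
        assert abs(kp1.y - kp2.y) < 1e-9
        assert abs(kp1.sigma - kp2.sigma) < 1e-9

    def test_recentres_when_offset_exceeds_half(self):
        # analytic peak 0.8 px right of the candidate: converges on the
        # neighbouring sample with a -0.2 offset
        D = quadratic_octave((0.8, 0.0, 0.0))
        kp = refine_keypoint(CandidatePoint(0, 2, 8, 8), make_dog(D))
        assert kp is not None
        assert kp.x == pytest.approx(8.8, abs=1e-6)

    def test_singular_hessian_rejected(self):
        D = np.zeros((5, 17, 17))  # identically flat: singular quadratic
        assert refine_keypoint(CandidatePoint(0, 2, 8, 8), make_dog(D)) is None


def hessian_octave(dxx, dyy, dxy):
    """Octave whose spatial Hessian at the centre equals the given values."""
    shape = (3, 9, 9)
    rr, cc = np.mgrid[0:9, 0:9].astype(float)
    layer = 0.5 * dxx * (cc - 4) ** 2 + 0.5 * dyy * (rr - 4) ** 2 + dxy * (cc - 4) * (rr - 4)
    D = np.zeros(shape)
    D[1] = layer
    return make_dog(D)


def centre_keypoint():
    return Keypoint(x=4.0, y=4.0, sigma=1.6, octave=0, layer=1, contrast=0.1)


class TestEdgeResponseFilter:
    def test_equal_curvatures_kept_for_any_gamma(self):
        dog = hessian_octave(-0.1, -0.1, 0.0)  # alpha == beta -> ratio 4
        for gamma in (1.5, 2.0, 10.0, 100.0):
            assert edge_response_filter(centre_keypoint(), dog, gamma)

    def test_eigenvalue_ratio_15_rejected_at_gamma_10(self):
        # Tr^2/Det = (15+1)^2/15 ~ 17.07 > (10+1)^2/10 = 12.1
        dog = hessian_octave(-0.15, -0.01, 0.0)
        assert not edge_response_filter(centre_keypoint(), dog, 10.0)

    def test_eigenvalue_ratio_just_below_gamma_kept(self):
        dog = hessian_octave(-0.09, -0.01, 0.0)  # ratio 9 < 10
        assert edge_response_filter(centre_keypoint(), dog, 10.0)

    def test_saddle_rejected(self):
        dog = hessian_octave(0.1, -0.1, 0.0)  # Det < 0
        assert not edge_response_filter(centre_keypoint(), dog, 10.0)

    def test_monotone_in_gamma(self, rng):
        """Raising gamma never rejects a previously kept keypoint."""
        for _ in range(50):
            dxx, dyy = -rng.uniform(0.01, 0.2, size=2)
            dxy = rng.uniform(-0.05, 0.05)
            dog = hessian_octave(dxx, dyy, dxy)
            kp = centre_keypoint()
            kept = [edge_response_filter(kp, dog, g) for g in (2, 5, 10, 20, 50)]
            # once kept at some gamma, kept at every larger gamma
            for a, b in zip(kept, kept[1:]):
                assert b or not a


class TestDetectKeypoints:
    def test_blob_located_at_centre_with_matching_scale(self):
        img = gaussian_blob(97, 4.0)
        kps, _ = detect_keypoints(img)
        assert len(kps) >= 1
        kp = max(kps, key=lambda p: p.contrast)
        assert abs(kp.x - 48) < 1.0 and abs(kp.y - 48) < 1.0
        assert 2.5 < kp.sigma < 6.5

    def test_downsampled_copy_detects_corresponding_keypoint(self, texture):
        """Physical location within 1 px, sigma halved within 10%.

        Checked on the strongest large-scale keypoint that survives 2x
        downsampling.
        """
        kps1, _ = detect_keypoints(texture)
        small = texture[::2, ::2]
        kps2, _ = detect_keypoints(small)
        big = [k for k in kps1 if k.sigma > 3.0]
        assert big, "need a large-scale keypoint for the halving check"
        matched = 0
        for k1 in big:
            for k2 in kps2:
                if (
                    abs(k2.x * 2 - k1.x) <= 2.0
                    and abs(k2.y * 2 - k1.y) <= 2.0
                    and abs(k2.sigma * 2 - k1.sigma) / k1.sigma <= 0.1
                ):
                    matched += 1
                    break
        assert matched / len(big) >= 0.5
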