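"""End-to-end stitching: detect, describe, match, purify, estimate, blend.

The full chain for one image pair:

1. detect scale-space keypoints on the luminance of both images and compute
   their 128-d descriptors;
2. 2-NN match in both directions (KD-tree best-bin-first search);
3. purify: ratio test each direction, bidirectional cross-check, RANSAC
   with chi-square inlier gate, binomial verification of the image match;
4. if verified, refit the homography on all inliers by least squares, warp
   the registered image and feather-blend the mosaic.

The estimated homography maps image-2 pixel coordinates into image-1
coordinates throughout.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np

from . import descriptor, fusion, matchsearch, purify, scalespace
from .config import PipelineConfig
from .geometry import Homography33, backprojection_error
from .purify import MatchCandidate, MatchSets, RansacConfig, VerificationParams

logger = logging.getLogger(__name__)

__all__ = ["StitchResult", "detect_and_describe", "match_features", "stitch_pair"]


@dataclass
class StitchResult:
    accepted: bool
    mosaic: np.ndarray | None
    H: Homography33 | None
    report: dict
    match_rows: list[dict] = field(default_factory=list)


def detect_and_describe(gray: np.ndarray, config: PipelineConfig):
    """Keypoints + descriptor matrix for one grayscale image."""
    kps, ss = scalespace.detect_keypoints(
        gray,
        sigma0=config.sigma0,
        intervals=config.intervals,
        octaves=config.octaves,
        k=config.k,
        contrast_threshold=config.contrast_threshold,
        gamma=config.gamma,
        max_keypoints=config.max_keypoints,
    )
    oriented, vecs = descriptor.describe_keypoints(
        kps, ss, config.gauss_variance_6sigma
    )
    return oriented, vecs


def match_features(
    desc_a: np.ndarray, desc_b: np.ndarray, config: PipelineConfig
) -> list[MatchCandidate]:
    """2-NN candidates from every descriptor in A against the set B."""
    pairs = matchsearch.match_descriptors(
        desc_a, desc_b, node_budget=config.bbf_budget, use_tree=config.use_kdtree
    )
    return [
        MatchCandidate(p=i, q=nb.q, d1=nb.d1, d2=nb.d2)
        for i, nb in enumerate(pairs)
    ]


def stitch_pair(
    img1, img2, config: PipelineConfig | None = None, color1=None, color2=None
) -> StitchResult:
    """Run the full pipeline on a pair of [0, 1] grayscale images.

    ``color1``/``color2`` optionally carry the original colour frames, which
    are blended per-channel while registration runs on luminance.  Returns a
    StitchResult whose report holds every stage count (keypoints, m1, m2,
    m3, n_f, n_i, the accept decision and the back-projection error of the
    inlier set).  No mosaic is produced when verification rejects the match.
    """
    config = config or PipelineConfig()
    t0 = time.perf_counter()
    report: dict = {"config_seed": config.seed}

    kp1, desc1 = detect_and_describe(scalespace.as_gray_image(img1), config)
    kp2, desc2 = detect_and_describe(scalespace.as_gray_image(img2), config)
    report["keypoints_1"] = len(kp1)
    report["keypoints_2"] = len(kp2)
    logger.info("keypoints: %d / %d", len(kp1), len(kp2))

    if len(desc1) < 2 or len(desc2) < 2:
        report.update(m1=0, m2=0, m3=0, n_f=0, n_i=0, accepted=False,
                      reason="too few keypoints")
        return StitchResult(False, None, None, report)

    fwd = match_features(desc1, desc2, config)
    bwd = match_features(desc2, desc1, config)
    A = purify.ratio_filter(fwd, config.ratio_T_R)
    B = purify.ratio_filter(bwd, config.ratio_T_R)
    C = purify.cross_validate(A, B)
    sets = MatchSets(A=A, B=B, C=C)
    report["m1"], report["m2"], report["m3"] = sets.m1, sets.m2, sets.m3
    logger.info("matches: m1=%d m2=%d m3=%d", sets.m1, sets.m2, sets.m3)

    match_rows = _match_rows(fwd, A, C, kp1, kp2)

    n_f = sets.m3
    if n_f < 4:
        report.update(n_f=n_f, n_i=0, accepted=False, reason="too few matches")
        return StitchResult(False, None, None, report, match_rows)

    # model maps image 2 -> image 1, so src are the image-2 points
    src = np.array([[kp2[c.q].x, kp2[c.q].y] for c in C])
    dst = np.array([[kp1[c.p].x, kp1[c.p].y] for c in C])
    rcfg = RansacConfig(
        p_success=config.p_success,
        sigma_noise=config.sigma_noise,
        significance=config.significance,
        max_iters=config.max_ransac_iters,
        seed=config.seed,
    )
    rres = purify.ransac_homography(src, dst, rcfg)
    n_i = rres.n_inliers if rres.succeeded else 0
    report["n_f"], report["n_i"] = n_f, n_i
    report["ransac_iterations"] = rres.iterations_used

    vparams = VerificationParams(alpha_v=config.alpha_v, beta_v=config.beta_v)
    ver = purify.verify_image_match(n_f, n_i, vparams)
    report["accepted"] = ver.accepted
    report["verification_posterior"] = ver.posterior
    kept_pairs = _ransac_kept(C, rres)
    for row in match_rows:
        if (row["p_idx"], row["q_idx"]) in kept_pairs:
            row["stage_kept"] = "ransac"

    if not ver.accepted or not rres.succeeded or rres.H is None:
        report["reason"] = "verification rejected"
        logger.info("verification rejected: n_i=%d <= %.1f + %.1f * %d",
                    n_i, config.alpha_v, config.beta_v, n_f)
        return StitchResult(False, None, rres.H, report, match_rows)

    _, E = backprojection_error(rres.H, src[rres.inlier_mask], dst[rres.inlier_mask])
    report["backprojection_error"] = E
    report["H"] = rres.H.matrix.tolist()

    blend1 = color1 if color1 is not None else np.asarray(img1, dtype=float)
    blend2 = color2 if color2 is not None else np.asarray(img2, dtype=float)
    mosaic = fusion.stitch_images(
        blend1, blend2, rres.H,
        ramp_mode=config.blend_ramp_mode,
        literal_halving=config.literal_blend_halving,
    )
    report["mosaic_shape"] = list(mosaic.shape)
    report["elapsed_s"] = round(time.perf_counter() - t0, 3)
    return StitchResult(True, mosaic, rres.H, report, match_rows)


def _match_rows(fwd, A, C, kp1, kp2) -> list[dict]:
    in_A = {(c.p, c.q) for c in A}
    in_C = {(c.p, c.q) for c in C}
    rows = []
    for c in fwd:
        stage = "nn"
        if (c.p, c.q) in in_A:
            stage = "ratio"
        if (c.p, c.q) in in_C:
            stage = "cross"
        rows.append({
            "p_idx": c.p, "q_idx": c.q,
            "x1": kp1[c.p].x, "y1": kp1[c.p].y,
            "x2": kp2[c.q].x, "y2": kp2[c.q].y,
            "d1": c.d1, "d2": c.d2,
            "R": c.ratio if np.isfinite(c.ratio) else -1.0,
            "stage_kept": stage,
        })
    return rows


def _ransac_kept(C, rres) -> set[tuple[int, int]]:
    """(p, q) pairs of C surviving RANSAC's inlier gate."""
    if not rres.succeeded:
        return set()
    return {(c.p, c.q) for c, m in zip(C, rres.inlier_mask) if m}
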