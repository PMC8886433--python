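"""Two-stage purification of tentative feature matches.

Stage one screens candidate correspondences by the nearest/second-nearest
distance ratio (``R = d1/d2 < T_R``, default 0.65) in both matching
directions and keeps only the bidirectionally consistent pairs (a pair
``(p, q)`` survives when ``p`` selects ``q`` forward and ``q`` selects ``p``
backward).  Stage two runs RANSAC on the survivors: random 4-pair samples
determine candidate homographies, pairs whose squared transfer error falls
below a chi-square-derived threshold ``t^2`` count as inliers, the required
sample count adapts to the best inlier fraction seen, and the final model is
a least-squares refit on the maximal inlier set.  Whether the two images
match at all is then decided by a binomial-model verification: the inlier
count among ``n_f`` tentative matches must exceed ``alpha + beta * n_f``
(``alpha = 8.0``, ``beta = 0.3``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import Homography33, apply_homography, backprojection_error, solve_dlt

logger = logging.getLogger(__name__)

__all__ = [
    "MatchCandidate",
    "MatchSets",
    "RansacConfig",
    "RansacResult",
    "VerificationParams",
    "VerificationResult",
    "ratio_filter",
    "cross_validate",
    "ransac_iterations",
    "inlier_threshold",
    "ransac_homography",
    "verify_image_match",
]

RATIO_THRESHOLD = 0.65
RANSAC_SAMPLE_SIZE = 4
#: Iterations without an inlier-count improvement before stopping early.
N_STALL = 200


@dataclass(frozen=True)
class MatchCandidate:
    """A tentative correspondence with its distance-ratio evidence."""

    p: int  # keypoint index in the query image
    q: int  # nearest-neighbour keypoint index in the target image
    d1: float
    d2: float

    @property
    def ratio(self) -> float:
        """R = d1 / d2; in [0, 1] whenever d2 > 0."""
        return self.d1 / self.d2 if self.d2 > 0 else math.inf


@dataclass
class MatchSets:
    """Forward set A, backward set B, and their bidirectional intersection C."""

    A: list[MatchCandidate]
    B: list[MatchCandidate]
    C: list[MatchCandidate]

    @property
    def m1(self) -> int:
        return len(self.A)

    @property
    def m2(self) -> int:
        return len(self.B)

    @property
    def m3(self) -> int:
        return len(self.C)


@dataclass
class RansacConfig:
    p_success: float = 0.99
    sigma_noise: float = 1.0  # assumed localisation noise std, px
    significance: float = 0.01
    max_iters: int = 2000
    seed: int = 0
    n_stall: int = N_STALL

    def __post_init__(self):
        if not 0.0 < self.p_success < 1.0:
            raise ValueError("p_success must lie in (0, 1)")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")
        if not 0.0 < self.significance < 1.0:
            raise ValueError("significance must lie in (0, 1)")


@dataclass
class RansacResult:
    H: Homography33 | None
    inlier_mask: np.ndarray
    X: int  # best inlier count (the MAX bookkeeping)
    iterations_used: int
    succeeded: bool = True

    @property
    def n_inliers(self) -> int:
        return int(self.inlier_mask.sum())


@dataclass
class VerificationParams:
    alpha_v: float = 8.0
    beta_v: float = 0.3
    p1: float = 0.6  # P(inlier | images truly match)
    p0: float = 0.1  # P(inlier | images do not match)
    prior_match: float = 1e-6  # P(m = 1)
    p_min: float = 0.999

    def __post_init__(self):
        if not 0.0 < self.p0 < self.p1 < 1.0:
            raise ValueError("need 0 < p0 < p1 < 1")


@dataclass
class VerificationResult:
    n_f: int
    n_i: int
    accepted: bool
    posterior: float = field(default=0.0)


def ratio_filter(
    pairs: list[MatchCandidate], threshold: float = RATIO_THRESHOLD
) -> list[MatchCandidate]:
    """Keep candidates whose distance ratio is strictly below the threshold.

    An ambiguous match (nearest almost as far as second-nearest) has a ratio
    near 1 and is discarded.  Candidates with ``d2 == 0`` (duplicate
    descriptors) cannot be scored and are rejected with a warning.
    """
    kept: list[MatchCandidate] = []
    for c in pairs:
        if c.d2 <= 0:
            logger.warning("degenerate second-nearest distance 0 for p=%d; dropped", c.p)
            continue
        if c.ratio < threshold:
            kept.append(c)
    return kept


def cross_validate(
    A: list[MatchCandidate], B: list[MatchCandidate]
) -> list[MatchCandidate]:
    """Bidirectional consistency: keep (p, q) in A when (q, p) is in B.

    Output order follows A.
    """
    back = {(c.p, c.q) for c in B}
    return [c for c in A if (c.q, c.p) in back]


def ransac_iterations(
    p_success: float, inlier_fraction: float, sample_size: int = RANSAC_SAMPLE_SIZE
) -> int:
    """Samples needed to draw one all-inlier minimal set with given confidence.

    ``N = log(1 - p) / log(1 - w^m)`` rounded up, where ``w`` is the inlier
    fraction and ``m`` the minimal sample size.
    """
    if not 0.0 < p_success < 1.0:
        raise ValueError("p_success must lie in (0, 1)")
    if not 0.0 < inlier_fraction <= 1.0:
        raise ValueError("inlier_fraction must lie in (0, 1]")
    w_m = inlier_fraction**sample_size
    if w_m >= 1.0:
        return 1
    if w_m <= 0.0:
        return np.iinfo(np.int64).max
    return int(math.ceil(math.log(1.0 - p_success) / math.log(1.0 - w_m)))


def inlier_threshold(cfg: RansacConfig) -> float:
    """Squared-distance gate separating inliers from exterior points.

    Under Gaussian localisation noise of std ``sigma`` the squared 2-D
    transfer error is ``sigma^2 chi^2_2``; the gate is the chi-square
    quantile at confidence ``1 - significance`` scaled by ``sigma^2``
    (9.210 sigma^2 at significance 0.01).
    """
    return float(stats.chi2.ppf(1.0 - cfg.significance, df=2)) * cfg.sigma_noise**2


def _sample_is_collinear(pts: np.ndarray) -> bool:
    """True if any 3 of the 4 points are (near-)collinear."""
    span = pts.max(axis=0) - pts.min(axis=0)
    diag2 = float(span @ span)
    if diag2 <= 0:
        return True
    for a in range(2):
        for b in range(a + 1, 3):
            for c in range(b + 1, 4):
                v1 = pts[b] - pts[a]
                v2 = pts[c] - pts[a]
                area2 = abs(v1[0] * v2[1] - v1[1] * v2[0])
                if area2 < 1e-6 * diag2:
                    return True
    return False


def ransac_homography(src, dst, cfg: RansacConfig | None = None) -> RansacResult:
    """Robust homography fit with adaptive sampling and least-squares refit.

    Parameters
    ----------
    src, dst : (n, 2) arrays, n >= 4
        Bidirectionally screened correspondences; the model maps src -> dst.
    cfg : RansacConfig
        Seeded; identical inputs and seed give identical results.

    Returns
    -------
    RansacResult
        ``succeeded`` is False when no sample produced >= 4 inliers; the
        final ``H`` is refit by least squares on the maximal inlier set and
        the mask recomputed under the refit model.
    """
    cfg = cfg or RansacConfig()
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    n = len(src)
    if n < RANSAC_SAMPLE_SIZE:
        raise ValueError(f"insufficient correspondences: {n} < {RANSAC_SAMPLE_SIZE}")
    rng = np.random.default_rng(cfg.seed)
    t2 = inlier_threshold(cfg)

    best_mask = np.zeros(n, dtype=bool)
    best_X = 0
    n_required = cfg.max_iters
    iters = 0
    since_improved = 0
    while iters < min(n_required, cfg.max_iters) and since_improved < cfg.n_stall:
        iters += 1
        since_improved += 1
        pick = rng.choice(n, size=RANSAC_SAMPLE_SIZE, replace=False)
        if _sample_is_collinear(src[pick]) or _sample_is_collinear(dst[pick]):
            continue
        try:
            H = solve_dlt(src[pick], dst[pick])
        except (ValueError, np.linalg.LinAlgError):
            continue
        try:
            d2, _ = backprojection_error(H, src, dst)
        except ValueError:
            continue
        mask = d2 < t2
        X = int(mask.sum())
        if X > best_X:  # the MAX update rule
            best_X, best_mask = X, mask
            since_improved = 0
            eps_hat = 1.0 - X / n
            n_required = ransac_iterations(
                cfg.p_success, max(1.0 - eps_hat, 1e-6), RANSAC_SAMPLE_SIZE
            )

    if best_X < RANSAC_SAMPLE_SIZE:
        logger.warning("RANSAC failed: best consensus %d < 4", best_X)
        return RansacResult(
            H=None, inlier_mask=np.zeros(n, dtype=bool), X=best_X,
            iterations_used=iters, succeeded=False,
        )

    # least-squares refit on the maximal inlier set; one mask/refit round so
    # the reported mask is consistent with the reported model
    mask = best_mask
    H = None
    for _ in range(2):
        try:
            H = solve_dlt(src[mask], dst[mask])
        except ValueError:
            break
        d2, _ = backprojection_error(H, src, dst)
        new_mask = d2 < t2
        if new_mask.sum() < RANSAC_SAMPLE_SIZE or np.array_equal(new_mask, mask):
            mask = new_mask if new_mask.sum() >= RANSAC_SAMPLE_SIZE else mask
            break
        mask = new_mask
    if H is None:
        return RansacResult(
            H=None, inlier_mask=np.zeros(n, dtype=bool), X=best_X,
            iterations_used=iters, succeeded=False,
        )
    return RansacResult(
        H=H, inlier_mask=mask, X=best_X, iterations_used=iters, succeeded=True
    )


def verify_image_match(
    n_f: int, n_i: int, params: VerificationParams | None = None
) -> VerificationResult:
    """Decide whether two images genuinely overlap.

    The operational rule is linear: accept iff ``n_i > alpha + beta * n_f``.
    For diagnostics, the binomial-model posterior probability of a true match
    is also reported: with inlier counts distributed ``B(n_f, p1)`` under a
    true match and ``B(n_f, p0)`` otherwise, and a small prior for a true
    match, Bayes' rule gives ``P(match | n_i)``.
    """
    params = params or VerificationParams()
    if not 0 <= n_i <= n_f:
        raise ValueError("need 0 <= n_i <= n_f")
    accepted = n_i > params.alpha_v + params.beta_v * n_f

    like1 = stats.binom.pmf(n_i, n_f, params.p1) if n_f > 0 else 1.0
    like0 = stats.binom.pmf(n_i, n_f, params.p0) if n_f > 0 else 1.0
    num = like1 * params.prior_match
    den = num + like0 * (1.0 - params.prior_match)
    posterior = float(num / den) if den > 0 else 0.0
    return VerificationResult(n_f=n_f, n_i=n_i, accepted=bool(accepted), posterior=posterior)
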