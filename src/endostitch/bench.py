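"""Planted-truth benchmark of the purification cascade.

On labelled planted correspondence sets the three columns of the standard
comparison can be measured exactly: precision of the raw tentative matches
("before"), of RANSAC applied directly to the raw matches ("RANSAC only"),
and of the full cascade (ratio test + cross-check + RANSAC, "improved").
Each column reports surviving-match counts (total/correct) and precision;
the expected pattern is a strictly increasing precision across the columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import purify
from .geometry import apply_homography
from .purify import MatchCandidate, RansacConfig
from .synthetic import PlantedMatchSpec, PlantedMatches, generate_matches

__all__ = ["StageResult", "BenchRow", "purification_stages", "run_benchmark"]


@dataclass
class StageResult:
    total: int
    correct: int

    @property
    def precision(self) -> float:
        return self.correct / self.total if self.total else 0.0


@dataclass
class BenchRow:
    seed: int
    before: StageResult
    ransac_only: StageResult
    improved: StageResult


def _candidates(pm: PlantedMatches, mutual_only: bool = False) -> list[MatchCandidate]:
    return [
        MatchCandidate(p=i, q=i, d1=float(pm.d1[i]), d2=float(pm.d2[i]))
        for i in range(len(pm))
        if not mutual_only or pm.mutual[i]
    ]


def _ransac_survivors(pm: PlantedMatches, idx: np.ndarray, cfg: RansacConfig) -> StageResult:
    if len(idx) < 4:
        return StageResult(total=0, correct=0)
    res = purify.ransac_homography(pm.src[idx], pm.dst[idx], cfg)
    if not res.succeeded:
        return StageResult(total=0, correct=0)
    surv = idx[res.inlier_mask]
    return StageResult(total=len(surv), correct=int(pm.labels[surv].sum()))


def purification_stages(pm: PlantedMatches, ransac_cfg: RansacConfig | None = None,
                        ratio_threshold: float = purify.RATIO_THRESHOLD) -> BenchRow:
    """Measure all three purification columns on one planted set."""
    cfg = ransac_cfg or RansacConfig()
    n = len(pm)
    before = StageResult(total=n, correct=int(pm.labels.sum()))

    ransac_only = _ransac_survivors(pm, np.arange(n), cfg)

    A = purify.ratio_filter(_candidates(pm), ratio_threshold)
    B = purify.ratio_filter(_candidates(pm, mutual_only=True), ratio_threshold)
    C = purify.cross_validate(A, B)
    idx = np.array([c.p for c in C], dtype=int)
    improved = _ransac_survivors(pm, idx, cfg)

    return BenchRow(seed=-1, before=before, ransac_only=ransac_only, improved=improved)


def run_benchmark(
    n_seeds: int = 20,
    base_seed: int = 0,
    spec: PlantedMatchSpec | None = None,
) -> list[BenchRow]:
    """Three-column purification comparison over several planted sets."""
    rows: list[BenchRow] = []
    base = spec or PlantedMatchSpec()
    for s in range(n_seeds):
        seed = base_seed + s
        pm = generate_matches(
            PlantedMatchSpec(
                n_inliers=base.n_inliers,
                n_outliers=base.n_outliers,
                sigma=base.sigma,
                coord_range=base.coord_range,
                seed=seed,
                near_miss_fraction=base.near_miss_fraction,
            )
        )
        cfg = RansacConfig(sigma_noise=max(base.sigma, 0.5), seed=seed)
        row = purification_stages(pm, cfg)
        row.seed = seed
        rows.append(row)
    return rows


def corner_transfer_error(H_est, H_true, shape: tuple[int, int]) -> float:
    """Max distance between estimated and true transfers of the 4 corners."""
    h, w = shape
    corners = np.array([[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]])
    a = apply_homography(H_est, corners)
    b = apply_homography(H_true, corners)
    return float(np.sqrt(((a - b) ** 2).sum(axis=1)).max())
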