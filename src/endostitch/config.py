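"""Pipeline configuration: every tunable with its default, validated on load.

Defaults are the operating point of the stitching method: base scale 1.6 and
3 intervals per octave for detection, contrast cut 0.03, edge-curvature
ratio 10, ratio-test gate 0.65, BBF budget of 200 leaf visits, RANSAC
confidence 0.99 with significance 0.01 and 1 px assumed localisation noise,
and the linear verification rule with alpha 8.0, beta 0.3.

Configs load from flat TOML files (``key = value``); unknown keys are
rejected so typos cannot silently fall back to defaults.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass
from pathlib import Path

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # scale space / detection
    sigma0: float = 1.6
    intervals: int = 3
    k_literal_2: bool = False  # use the literal k = 2 instead of 2**(1/intervals)
    contrast_threshold: float = 0.03
    gamma: float = 10.0
    octaves: int | None = None
    max_keypoints: int | None = 600
    # descriptor
    gauss_variance_6sigma: bool = False
    # matching
    ratio_T_R: float = 0.65
    bbf_budget: int = 200
    use_kdtree: bool = True
    # RANSAC
    p_success: float = 0.99
    significance: float = 0.01
    sigma_noise: float = 1.0
    max_ransac_iters: int = 2000
    # verification
    alpha_v: float = 8.0
    beta_v: float = 0.3
    # fusion
    blend_ramp_mode: str = "axis"  # or "distance"
    literal_blend_halving: bool = False
    # reproducibility
    seed: int = 0

    def __post_init__(self):
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.intervals < 1:
            raise ValueError("intervals must be >= 1")
        if not 0 < self.ratio_T_R <= 1:
            raise ValueError("ratio_T_R must lie in (0, 1]")
        if self.bbf_budget < 1:
            raise ValueError("bbf_budget must be >= 1")
        if not 0 < self.p_success < 1:
            raise ValueError("p_success must lie in (0, 1)")
        if not 0 < self.significance < 1:
            raise ValueError("significance must lie in (0, 1)")
        if self.sigma_noise <= 0:
            raise ValueError("sigma_noise must be positive")
        if self.gamma < 1:
            raise ValueError("gamma must be >= 1")
        if self.blend_ramp_mode not in ("axis", "distance"):
            raise ValueError("blend_ramp_mode must be 'axis' or 'distance'")

    @property
    def k(self) -> float:
        return 2.0 if self.k_literal_2 else 2.0 ** (1.0 / self.intervals)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kw) -> "PipelineConfig":
        return dataclasses.replace(self, **kw)
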