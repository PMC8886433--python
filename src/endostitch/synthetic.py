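"""Synthetic endoscope-like fixtures with known ground truth.

Two generators make every pipeline stage testable without real endoscope
footage:

``generate_pair``
    Renders a band-limited multi-octave value-noise texture (a stand-in for
    mucosal texture with controllable keypoint density), views it through
    two camera poses related by a known homography, and applies the
    signatures of endoscope frames — a circular field-of-view vignette,
    per-frame gain/offset jitter, and additive sensor noise.

``generate_matches``
    Plants a labelled correspondence set under a known homography: inliers
    are mapped points perturbed by Gaussian localisation noise; outliers are
    a mix of independent uniform mismatches and "near-miss" mismatches
    displaced a small distance from the true location, the way repetitive
    tissue texture produces them.  Synthesised ratio-test distances and
    mutuality flags let the full purification cascade run on planted sets.

All generators are pure functions of their seed and spec.  The homography
convention matches the rest of the package: ``H_true`` maps image-2 pixel
coordinates into image-1 coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import Homography33, apply_homography

__all__ = [
    "SceneSpec",
    "PlantedMatchSpec",
    "PlantedMatches",
    "value_noise",
    "vignette_mask",
    "generate_pair",
    "generate_matches",
    "translation_homography",
    "random_viewpoint_homography",
]

MIN_OVERLAP = 0.25


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of a synthetic endoscope frame pair."""

    seed: int = 0
    size: tuple[int, int] = (180, 240)  # (height, width)
    texture_octaves: int = 5
    persistence: float = 0.85
    #: Sigmoid tone-curve gain applied to the latent scene; mucosal imagery
    #: is high-contrast, and without the stretch band-limited noise is too
    #: flat to carry a realistic keypoint density.  0 disables.
    contrast_gain: float = 8.0
    vignette_radius: float = 0.95  # fraction of half-diagonal of min side
    vignette_softness: float = 0.15
    gain_jitter: float = 0.05  # multiplicative brightness change, frame 2
    offset_jitter: float = 0.02  # additive brightness change, frame 2
    noise_std: float = 0.0  # additive Gaussian sensor noise


@dataclass(frozen=True)
class PlantedMatchSpec:
    """Parameters of a planted labelled correspondence set."""

    n_inliers: int = 120
    n_outliers: int = 80
    sigma: float = 1.0  # localisation noise std, px
    coord_range: tuple[int, int] = (300, 400)  # (height, width) of both frames
    seed: int = 0
    margin: float = 10.0
    #: Fraction of outliers that are near-miss mismatches (true location plus
    #: a small offset), the rest being independent uniform points.  Repetitive
    #: texture makes near-miss mismatches the dominant real failure mode.
    near_miss_fraction: float = 0.4
    near_miss_radius: tuple[float, float] = (1.5, 12.0)
    #: Ratio-test distance model: inlier ratios concentrate well below the
    #: 0.65 gate, outlier ratios near 1; mutual-match probabilities likewise
    #: separate the populations for the cross-check stage.
    inlier_ratio_beta: tuple[float, float] = (4.0, 5.0)  # mean ~0.44
    outlier_ratio_beta: tuple[float, float] = (8.0, 2.0)  # mean 0.8
    inlier_mutual_p: float = 0.95
    outlier_mutual_p: float = 0.3


@dataclass
class PlantedMatches:
    """Labelled planted correspondences (image-2 points -> image-1 points)."""

    src: np.ndarray  # (n, 2) points in image 2
    dst: np.ndarray  # (n, 2) points in image 1
    labels: np.ndarray  # (n,) bool, True = inlier
    d1: np.ndarray  # synthetic nearest distances
    d2: np.ndarray  # synthetic second-nearest distances
    mutual: np.ndarray  # (n,) bool, True = survives the backward check
    H_true: Homography33

    def __len__(self) -> int:
        return len(self.labels)


def value_noise(
    shape: tuple[int, int], octaves: int, persistence: float, rng: np.random.Generator
) -> np.ndarray:
    """Band-limited multi-octave value noise in [0, 1].

    Each octave is white noise on a coarse lattice bilinearly upsampled to
    full resolution; amplitudes decay by ``persistence`` per octave.
    """
    h, w = shape
    out = np.zeros(shape)
    amp_total = 0.0
    for o in range(octaves):
        cells = 4 * 2**o
        coarse = rng.random((min(cells, h), min(cells, w)))
        zoom = (h / coarse.shape[0], w / coarse.shape[1])
        layer = ndimage.zoom(coarse, zoom, order=1, mode="reflect", grid_mode=True)
        amp = persistence**o
        out += amp * layer[:h, :w]
        amp_total += amp
    out /= amp_total
    lo, hi = out.min(), out.max()
    return (out - lo) / (hi - lo) if hi > lo else out


def vignette_mask(shape: tuple[int, int], radius: float, softness: float) -> np.ndarray:
    """Circular field-of-view falloff with a smoothstep edge.

    ``radius`` is a fraction of half the image diagonal (the FOV circle of
    an endoscope still is clipped by the sensor frame, so only the corners
    darken); intensity is 1 inside the disc, smoothstepping to 0 across
    ``softness`` of the radius.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(yy - (h - 1) / 2.0, xx - (w - 1) / 2.0)
    r0 = radius * np.hypot(h, w) / 2.0
    soft = max(softness * r0, 1e-6)
    t = np.clip((r0 - r) / soft, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def translation_homography(tx: float, ty: float = 0.0) -> Homography33:
    return Homography33([[1, 0, tx], [0, 1, ty], [0, 0, 1]])


def random_viewpoint_homography(
    rng: np.random.Generator,
    shape: tuple[int, int],
    max_translation: float = 40.0,
    max_rotation_deg: float = 4.0,
    max_perspective: float = 1e-4,
) -> Homography33:
    """A mild random viewpoint change about the image centre.

    Rotation, translation and a small projective component of the magnitude
    produced by slow endoscope motion over near-planar tissue.
    """
    h, w = shape
    ang = np.radians(rng.uniform(-max_rotation_deg, max_rotation_deg))
    tx = rng.uniform(0.3, 1.0) * max_translation * rng.choice([-1, 1])
    ty = rng.uniform(-0.5, 0.5) * max_translation
    px, py = rng.uniform(-max_perspective, max_perspective, size=2)
    c, s = np.cos(ang), np.sin(ang)
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    T1 = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1.0]])
    R = np.array([[c, -s, tx], [s, c, ty], [px, py, 1.0]])
    T2 = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1.0]])
    return Homography33(T2 @ R @ T1)


def _overlap_fraction(shape: tuple[int, int], H: Homography33) -> float:
    """Fraction of image 1 visible in image 2 (grid-sampled)."""
    h, w = shape
    gx, gy = np.meshgrid(np.linspace(0, w - 1, 24), np.linspace(0, h - 1, 24))
    pts1 = np.column_stack([gx.ravel(), gy.ravel()])
    pts2 = apply_homography(H.inverse(), pts1)
    inside = (
        (pts2[:, 0] >= 0) & (pts2[:, 0] <= w - 1)
        & (pts2[:, 1] >= 0) & (pts2[:, 1] <= h - 1)
    )
    return float(inside.mean())


def generate_pair(
    spec: SceneSpec, H_true: Homography33
) -> tuple[np.ndarray, np.ndarray, Homography33]:
    """Render an overlapping image pair related by a known homography.

    Image 1 is a window onto the latent textured scene; image 2 samples the
    same scene through ``H_true`` (image-2 coords -> image-1 coords), then
    receives gain/offset jitter, additive noise and the circular vignette.

    Raises
    ------
    ValueError
        When less than 25% of image 1 remains visible in image 2 — such a
        pair is not stitchable by design.
    """
    frac = _overlap_fraction(spec.size, H_true)
    if frac < MIN_OVERLAP:
        raise ValueError(
            f"overlap {frac:.0%} below the {MIN_OVERLAP:.0%} minimum; "
            "reduce the viewpoint change"
        )
    h, w = spec.size
    rng = np.random.default_rng(spec.seed)
    pad = 96
    scene = value_noise((h + 2 * pad, w + 2 * pad), spec.texture_octaves,
                        spec.persistence, rng)
    if spec.contrast_gain > 0:
        scene = 1.0 / (1.0 + np.exp(-spec.contrast_gain * (scene - 0.5)))

    img1 = scene[pad : pad + h, pad : pad + w].copy()

    X, Y = np.meshgrid(np.arange(w, dtype=float), np.arange(h, dtype=float))
    pts2 = np.column_stack([X.ravel(), Y.ravel()])
    src = apply_homography(H_true, pts2)  # image-2 pixel -> scene (image-1) coords
    coords = np.array([src[:, 1].ravel() + pad, src[:, 0].ravel() + pad])
    img2 = ndimage.map_coordinates(scene, coords, order=1, mode="constant",
                                   cval=0.0).reshape(h, w)

    gain = 1.0 + rng.uniform(-spec.gain_jitter, spec.gain_jitter)
    offset = rng.uniform(-spec.offset_jitter, spec.offset_jitter)
    img2 = img2 * gain + offset
    if spec.noise_std > 0:
        img1 = img1 + rng.normal(0.0, spec.noise_std, img1.shape)
        img2 = img2 + rng.normal(0.0, spec.noise_std, img2.shape)

    vig = vignette_mask(spec.size, spec.vignette_radius, spec.vignette_softness)
    img1 = np.clip(img1 * vig, 0.0, 1.0)
    img2 = np.clip(img2 * vig, 0.0, 1.0)
    return img1, img2, H_true


def generate_matches(spec: PlantedMatchSpec) -> PlantedMatches:
    """Plant a labelled correspondence set under a known homography.

    Inliers are image-2 points mapped by ``H_true`` into image 1 plus
    Gaussian localisation noise.  Outliers mix independent uniform points
    with near-miss mismatches (true location plus a uniform annulus offset).
    Synthetic nearest/second-nearest distances and mutuality flags are drawn
    from separated distributions for the two populations so the ratio and
    cross-check stages operate on planted sets exactly as on real matches.
    """
    n_in, n_out = spec.n_inliers, spec.n_outliers
    if n_in < 0 or n_out < 0 or n_in + n_out < 4:
        raise ValueError("need n_inliers + n_outliers >= 4, both non-negative")
    h, w = spec.coord_range
    rng = np.random.default_rng(spec.seed)
    H_true = random_viewpoint_homography(rng, (h, w))

    m = spec.margin
    n = n_in + n_out
    src = np.column_stack([
        rng.uniform(m, w - m, size=n),
        rng.uniform(m, h - m, size=n),
    ])
    dst = apply_homography(H_true, src)
    labels = np.zeros(n, dtype=bool)
    labels[:n_in] = True

    dst[:n_in] += rng.normal(0.0, spec.sigma, size=(n_in, 2))

    n_near = int(round(spec.near_miss_fraction * n_out))
    lo, hi = spec.near_miss_radius
    r = rng.uniform(lo, hi, size=n_near)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_near)
    dst[n_in : n_in + n_near] += np.column_stack([r * np.cos(phi), r * np.sin(phi)])
    n_unif = n_out - n_near
    dst[n_in + n_near :] = np.column_stack([
        rng.uniform(m, w - m, size=n_unif),
        rng.uniform(m, h - m, size=n_unif),
    ])

    d2 = rng.uniform(0.45, 0.75, size=n)
    ratio = np.empty(n)
    a_in, b_in = spec.inlier_ratio_beta
    a_out, b_out = spec.outlier_ratio_beta
    ratio[:n_in] = rng.beta(a_in, b_in, size=n_in)
    ratio[n_in:] = rng.beta(a_out, b_out, size=n_out)
    d1 = ratio * d2

    mutual = np.empty(n, dtype=bool)
    mutual[:n_in] = rng.random(n_in) < spec.inlier_mutual_p
    mutual[n_in:] = rng.random(n_out) < spec.outlier_mutual_p

    perm = rng.permutation(n)
    return PlantedMatches(
        src=src[perm], dst=dst[perm], labels=labels[perm],
        d1=d1[perm], d2=d2[perm], mutual=mutual[perm], H_true=H_true,
    )
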