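"""Gaussian/DoG scale space, extremum detection and keypoint refinement.

The scale space of an image ``I`` is the family ``L(x, y, sigma) =
G(sigma) * I`` of Gaussian blurs.  Differences of adjacent blurs,
``D(sigma) = L(k sigma) - L(sigma)``, approximate the scale-normalised
Laplacian ``(k - 1) sigma^2 lap(G) * I`` and respond maximally at blob-like
structures whose size matches sigma.  Candidate keypoints are the strict
extrema of ``D`` over their 26 neighbours in (x, y, scale); they are then
refined to sub-pixel/sub-scale accuracy by a second-order Taylor fit,
rejected when the refined response is weak (low contrast) or when the 2-D
spatial Hessian marks them as edge-like (one dominant principal curvature).

Layout: each octave holds ``intervals + 3`` Gaussian layers whose in-octave
scales are ``sigma0 * k**i``; successive octaves are downsampled by 2.
Coordinates are pixel units in the input image, x = column, y = row,
0-based; an octave-``o`` sample (row, col) maps back to ``(col, row) * 2**o``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "GrayImage",
    "ScaleSpace",
    "DogStack",
    "Keypoint",
    "CandidatePoint",
    "as_gray_image",
    "max_octaves",
    "build_scale_space",
    "detect_extrema",
    "refine_keypoint",
    "edge_response_filter",
    "detect_keypoints",
]

MIN_DETECT_SIZE = 16
#: Gaussian kernels are truncated at 4 standard deviations, reflected borders.
GAUSS_TRUNCATE = 4.0
#: Assumed blur already present in the input (camera / sensor smoothing).
ASSUMED_BLUR = 0.5


def as_gray_image(img) -> np.ndarray:
    """Validate and return a float grayscale image with values in [0, 1].

    RGB(A) input is converted with Rec. 601 luminance so that absolute
    thresholds (the 0.03 contrast cut) keep their meaning.
    """
    a = np.asarray(img, dtype=float)
    if a.ndim == 3:
        if a.shape[2] not in (3, 4):
            raise ValueError(f"expected RGB(A) last axis, got shape {a.shape}")
        a = a[..., 0] * 0.299 + a[..., 1] * 0.587 + a[..., 2] * 0.114
    if a.ndim != 2:
        raise ValueError(f"expected 2-D image, got shape {a.shape}")
    if not np.isfinite(a).all():
        raise ValueError("image contains non-finite values")
    if a.min() < -1e-9 or a.max() > 1 + 1e-9:
        raise ValueError("intensities must lie in [0, 1]; normalise on read")
    return np.clip(a, 0.0, 1.0)


# GrayImage is a plain ndarray in [0,1]; the alias documents intent in hints.
GrayImage = np.ndarray


@dataclass
class ScaleSpace:
    """Per-octave stacks of Gaussian layers with their in-octave scales."""

    octaves: list[np.ndarray]  # each (n_layers, h, w)
    sigmas: np.ndarray  # in-octave absolute scales, shared across octaves
    sigma0: float
    k: float
    intervals: int

    def layer(self, octave: int, index: int) -> np.ndarray:
        return self.octaves[octave][index]

    def sigma_of(self, octave: int, index: float) -> float:
        """Absolute scale in input-image pixels (fractional index allowed)."""
        return self.sigma0 * self.k ** float(index) * 2.0**octave


@dataclass
class DogStack:
    """Difference-of-Gaussian stacks, one fewer layer per octave."""

    octaves: list[np.ndarray]  # each (n_layers - 1, h, w)
    sigmas: np.ndarray
    sigma0: float
    k: float
    intervals: int


@dataclass(frozen=True)
class CandidatePoint:
    """Raw 26-neighbour extremum sample in a DoG octave."""

    octave: int
    layer: int
    row: int
    col: int


@dataclass
class Keypoint:
    """Refined scale-space keypoint in input-image coordinates."""

    x: float  # column, px
    y: float  # row, px
    sigma: float  # absolute scale, px
    octave: int
    layer: int
    contrast: float  # |D(x_hat)|
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))  # (x, y, s)

    @property
    def pt(self) -> np.ndarray:
        return np.array([self.x, self.y])


def max_octaves(height: int, width: int) -> int:
    """Largest octave count keeping the top octave at least 8 px across."""
    return max(1, int(math.floor(math.log2(min(height, width)))) - 2)


def default_octaves(height: int, width: int) -> int:
    return max(1, int(math.floor(math.log2(min(height, width)))) - 3)


def _blur(img: np.ndarray, sigma: float) -> np.ndarray:
    if sigma < 1e-8:
        return img.copy()
    return ndimage.gaussian_filter(img, sigma, mode="reflect", truncate=GAUSS_TRUNCATE)


def build_scale_space(
    img: GrayImage,
    sigma0: float = 1.6,
    intervals: int = 3,
    octaves: int | None = None,
    k: float | None = None,
    assumed_blur: float = ASSUMED_BLUR,
) -> tuple[ScaleSpace, DogStack]:
    """Build the Gaussian pyramid and its DoG differences.

    Parameters
    ----------
    img : 2-D array in [0, 1]
        At least 16 x 16.
    sigma0 : float
        Base scale of the first layer of each octave, in that octave's pixels.
    intervals : int
        Layers per scale doubling; each octave gets ``intervals + 3`` Gaussian
        layers so every one of the ``intervals`` scales has a full 3x3x3 DoG
        neighbourhood.
    octaves : int, optional
        Defaults to ``floor(log2(min(h, w))) - 3``.
    k : float, optional
        Scale multiplier between adjacent layers.  Default ``2**(1/intervals)``
        (the geometric progression that makes an octave span a doubling);
        a literal ``k = 2`` is selectable for fidelity experiments but breaks
        the octave-doubling progression.
    assumed_blur : float
        Blur assumed already present in the input; the first layer is blurred
        by ``sqrt(sigma0^2 - assumed_blur^2)`` to land exactly at sigma0.

    Returns
    -------
    (ScaleSpace, DogStack)

    Raises
    ------
    ValueError
        Image smaller than 16 px, or ``octaves`` infeasible for the image
        size (the error names the maximum feasible count).
    """
    img = as_gray_image(img)
    h, w = img.shape
    if h < MIN_DETECT_SIZE or w < MIN_DETECT_SIZE:
        raise ValueError(f"image {h}x{w} too small; need >= {MIN_DETECT_SIZE} px")
    if sigma0 <= 0:
        raise ValueError("sigma0 must be positive")
    if intervals < 1:
        raise ValueError("intervals must be >= 1")
    feasible = max_octaves(h, w)
    if octaves is None:
        octaves = min(default_octaves(h, w), feasible)
    if octaves < 1:
        raise ValueError("octaves must be >= 1")
    if octaves > feasible:
        raise ValueError(
            f"image {h}x{w} supports at most {feasible} octaves, got {octaves}"
        )
    if k is None:
        k = 2.0 ** (1.0 / intervals)
    if k <= 1:
        raise ValueError("k must exceed 1")

    n_layers = intervals + 3
    sigmas = sigma0 * k ** np.arange(n_layers)

    base = _blur(img, math.sqrt(max(sigma0**2 - assumed_blur**2, 0.0)))
    gauss_octaves: list[np.ndarray] = []
    dog_octaves: list[np.ndarray] = []
    current = base
    for o in range(octaves):
        stack = np.empty((n_layers,) + current.shape)
        stack[0] = current
        for i in range(1, n_layers):
            # incremental blur: sigma_i from sigma_{i-1}
            inc = math.sqrt(sigmas[i] ** 2 - sigmas[i - 1] ** 2)
            stack[i] = _blur(stack[i - 1], inc)
        gauss_octaves.append(stack)
        dog_octaves.append(np.diff(stack, axis=0))
        # seed next octave from the layer at sigma0 * k**intervals
        current = stack[intervals][::2, ::2]

    ss = ScaleSpace(gauss_octaves, sigmas, sigma0, k, intervals)
    dog = DogStack(dog_octaves, sigmas, sigma0, k, intervals)
    return ss, dog


def detect_extrema(dog: DogStack) -> list[CandidatePoint]:
    """Strict 26-neighbour extrema of every DoG octave.

    A sample qualifies only if it is strictly greater than (or strictly less
    than) all 26 neighbours in its 3x3x3 cube; plateaus are never reported.
    Border rows/columns and the first/last layer of each octave are excluded.
    """
    footprint = np.ones((3, 3, 3), dtype=bool)
    footprint[1, 1, 1] = False
    out: list[CandidatePoint] = []
    for o, D in enumerate(dog.octaves):
        if D.shape[0] < 3:
            raise ValueError("need >= 3 DoG layers per octave for extremum detection")
        nb_max = ndimage.maximum_filter(D, footprint=footprint, mode="constant", cval=-np.inf)
        nb_min = ndimage.minimum_filter(D, footprint=footprint, mode="constant", cval=np.inf)
        is_ext = (D > nb_max) | (D < nb_min)
        is_ext[0] = is_ext[-1] = False
        is_ext[:, 0, :] = is_ext[:, -1, :] = False
        is_ext[:, :, 0] = is_ext[:, :, -1] = False
        for layer, row, col in zip(*np.nonzero(is_ext)):
            out.append(CandidatePoint(o, int(layer), int(row), int(col)))
    return out


def _dog_derivatives(D: np.ndarray, layer: int, row: int, col: int):
    """Central-difference gradient and Hessian in (x, y, s) order, unit step."""
    dx = 0.5 * (D[layer, row, col + 1] - D[layer, row, col - 1])
    dy = 0.5 * (D[layer, row + 1, col] - D[layer, row - 1, col])
    ds = 0.5 * (D[layer + 1, row, col] - D[layer - 1, row, col])
    v2 = 2.0 * D[layer, row, col]
    dxx = D[layer, row, col + 1] + D[layer, row, col - 1] - v2
    dyy = D[layer, row + 1, col] + D[layer, row - 1, col] - v2
    dss = D[layer + 1, row, col] + D[layer - 1, row, col] - v2
    dxy = 0.25 * (
        D[layer, row + 1, col + 1]
        - D[layer, row + 1, col - 1]
        - D[layer, row - 1, col + 1]
        + D[layer, row - 1, col - 1]
    )
    dxs = 0.25 * (
        D[layer + 1, row, col + 1]
        - D[layer + 1, row, col - 1]
        - D[layer - 1, row, col + 1]
        + D[layer - 1, row, col - 1]
    )
    dys = 0.25 * (
        D[layer + 1, row + 1, col]
        - D[layer + 1, row - 1, col]
        - D[layer - 1, row + 1, col]
        + D[layer - 1, row - 1, col]
    )
    g = np.array([dx, dy, ds])
    H = np.array([[dxx, dxy, dxs], [dxy, dyy, dys], [dxs, dys, dss]])
    return g, H


def refine_keypoint(
    cand: CandidatePoint,
    dog: DogStack,
    contrast_threshold: float = 0.03,
    max_iters: int = 5,
) -> Keypoint | None:
    """Sub-pixel/sub-scale refinement by a 3-D quadratic (Taylor) fit.

    Solves ``x_hat = -(d2D/dx2)^-1 (dD/dx)`` with finite differences; while
    any component of ``x_hat`` exceeds 0.5 the fit is re-centred on the
    neighbouring sample (up to ``max_iters`` times).  Accepts only candidates
    that converge inside the octave with refined response
    ``|D(x_hat)| >= contrast_threshold``; returns None otherwise.
    """
    D = dog.octaves[cand.octave]
    n_layers, h, w = D.shape
    layer, row, col = cand.layer, cand.row, cand.col
    x_hat = np.zeros(3)
    for _ in range(max_iters):
        if not (1 <= layer < n_layers - 1 and 1 <= row < h - 1 and 1 <= col < w - 1):
            logger.debug("candidate %s wandered outside octave; rejected", cand)
            return None
        g, Hess = _dog_derivatives(D, layer, row, col)
        try:
            x_hat = -np.linalg.solve(Hess, g)
        except np.linalg.LinAlgError:
            logger.debug("singular quadratic Hessian at %s; rejected", cand)
            return None
        if np.all(np.abs(x_hat) <= 0.5):
            break
        # shift toward the neighbouring sample indicated by the offset
        col += int(np.round(x_hat[0]))
        row += int(np.round(x_hat[1]))
        layer += int(np.round(x_hat[2]))
    else:
        logger.debug("refinement did not converge at %s; rejected", cand)
        return None

    contrast = D[layer, row, col] + 0.5 * float(g @ x_hat)
    if abs(contrast) < contrast_threshold:
        return None

    scale = 2.0**cand.octave
    return Keypoint(
        x=(col + x_hat[0]) * scale,
        y=(row + x_hat[1]) * scale,
        sigma=dog.sigma0 * dog.k ** (layer + x_hat[2]) * scale,
        octave=cand.octave,
        layer=layer,
        contrast=abs(contrast),
        offset=x_hat,
    )


def edge_response_filter(kp: Keypoint, dog: DogStack, gamma: float = 10.0) -> bool:
    """Principal-curvature (edge) test on the 2-D spatial Hessian.

    A keypoint sitting on an edge has one dominant principal curvature, so the
    eigenvalue ratio of the spatial Hessian is large.  With ``alpha = gamma *
    beta`` the bound ``Tr(H)^2 / Det(H) < (gamma + 1)^2 / gamma`` keeps points
    whose curvature ratio is below ``gamma``; saddle points (``Det <= 0``)
    are always rejected.  Returns True to keep.
    """
    D = dog.octaves[kp.octave]
    n_layers, h, w = D.shape
    layer = kp.layer
    row = int(round(kp.y / 2.0**kp.octave))
    col = int(round(kp.x / 2.0**kp.octave))
    if not (0 <= layer < n_layers and 1 <= row < h - 1 and 1 <= col < w - 1):
        return False
    v2 = 2.0 * D[layer, row, col]
    dxx = D[layer, row, col + 1] + D[layer, row, col - 1] - v2
    dyy = D[layer, row + 1, col] + D[layer, row - 1, col] - v2
    dxy = 0.25 * (
        D[layer, row + 1, col + 1]
        - D[layer, row + 1, col - 1]
        - D[layer, row - 1, col + 1]
        + D[layer, row - 1, col - 1]
    )
    tr = dxx + dyy
    det = dxx * dyy - dxy * dxy
    if det <= 0:
        return False
    return tr * tr / det < (gamma + 1.0) ** 2 / gamma


def detect_keypoints(
    img: GrayImage,
    sigma0: float = 1.6,
    intervals: int = 3,
    octaves: int | None = None,
    k: float | None = None,
    contrast_threshold: float = 0.03,
    gamma: float = 10.0,
    max_keypoints: int | None = None,
) -> tuple[list[Keypoint], ScaleSpace]:
    """Full detection chain: pyramid, extrema, refinement, edge rejection.

    Duplicate keypoints (same octave/position/scale after refinement) are
    collapsed.  When ``max_keypoints`` is given, the strongest-contrast
    keypoints are kept.  Returns the keypoints and the Gaussian scale space
    (needed downstream for orientation and description).
    """
    ss, dog = build_scale_space(img, sigma0, intervals, octaves, k)
    kps: list[Keypoint] = []
    seen: set[tuple] = set()
    for cand in detect_extrema(dog):
        kp = refine_keypoint(cand, dog, contrast_threshold)
        if kp is None:
            continue
        if not edge_response_filter(kp, dog, gamma):
            continue
        key = (kp.octave, round(kp.x, 1), round(kp.y, 1), round(kp.sigma, 2))
        if key in seen:
            continue
        seen.add(key)
        kps.append(kp)
    if max_keypoints is not None and len(kps) > max_keypoints:
        kps = sorted(kps, key=lambda p: -p.contrast)[:max_keypoints]
    logger.info("detected %d keypoints", len(kps))
    return kps, ss
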