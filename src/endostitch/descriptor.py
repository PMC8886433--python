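"""Keypoint orientation assignment and the 128-d gradient descriptor.

Each keypoint receives one or more dominant orientations from a 36-bin
histogram of gradient directions in a circle of radius 3 x 1.5 sigma,
magnitude-weighted and Gaussian-windowed; secondary peaks above 80% of the
maximum spawn auxiliary copies of the keypoint.  The descriptor then samples
the gradient field in a 4x4 grid of cells (side 3 sigma each) rotated to the
keypoint orientation, accumulating 8-direction histograms per cell with
trilinear interpolation — 16 x 8 = 128 components.  L2 normalisation, a 0.2
clamp, and renormalisation make the vector invariant to affine brightness
changes and robust to non-linear ones.

Gradients follow the central-difference convention
``theta = atan2(L(x, y+1) - L(x, y-1), L(x+1, y) - L(x-1, y))`` mapped to
[0, 360): with y pointing down the image, a vertical ramp has theta = 90.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .scalespace import Keypoint, ScaleSpace

logger = logging.getLogger(__name__)

__all__ = [
    "OrientedKeypoint",
    "Descriptor",
    "gradient_field",
    "assign_orientations",
    "compute_descriptor",
    "describe_keypoints",
]

N_ORI_BINS = 36
AUX_PEAK_RATIO = 0.8
N_CELLS = 4  # 4x4 spatial grid
N_DIR_BINS = 8  # 45 degrees each
DESCRIPTOR_LENGTH = N_CELLS * N_CELLS * N_DIR_BINS  # 128
CLAMP = 0.2
#: Orientation-histogram Gaussian width as a multiple of the keypoint scale.
ORI_SIGMA_FACTOR = 1.5
ORI_RADIUS_FACTOR = 3.0  # radius = 3 * (1.5 sigma)
#: Descriptor cell side as a multiple of the keypoint scale.
CELL_SIGMA_FACTOR = 3.0
#: Sampling window enlargement allowing for rotation of the 4x4 grid.
ROTATION_SLACK = math.sqrt(2.0)


@dataclass
class OrientedKeypoint(Keypoint):
    """Keypoint plus an orientation theta in degrees [0, 360)."""

    theta: float = 0.0

    @classmethod
    def from_keypoint(cls, kp: Keypoint, theta: float) -> "OrientedKeypoint":
        return cls(
            x=kp.x, y=kp.y, sigma=kp.sigma, octave=kp.octave, layer=kp.layer,
            contrast=kp.contrast, offset=kp.offset, theta=theta % 360.0,
        )


@dataclass
class Descriptor:
    """128-component unit feature vector.

    ``values`` is the final vector (unit L2 norm); ``clipped`` is the
    intermediate after the 0.2 clamp but before renormalisation, kept
    inspectable so the clamp contract can be checked.
    """

    values: np.ndarray
    parent: OrientedKeypoint
    clipped: np.ndarray | None = None


def gradient_field(layer: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel gradient magnitude and direction of a blurred layer.

    Central differences with unit spacing; the 1-px border is zeroed (no
    valid central difference there).  Directions in degrees [0, 360).
    """
    m = np.zeros_like(layer)
    theta = np.zeros_like(layer)
    dx = layer[1:-1, 2:] - layer[1:-1, :-2]
    dy = layer[2:, 1:-1] - layer[:-2, 1:-1]
    m[1:-1, 1:-1] = np.hypot(dx, dy)
    theta[1:-1, 1:-1] = np.degrees(np.arctan2(dy, dx)) % 360.0
    return m, theta


def _octave_coords(kp: Keypoint) -> tuple[float, float, float]:
    """Keypoint position and scale expressed in its octave's pixels."""
    s = 2.0**kp.octave
    return kp.x / s, kp.y / s, kp.sigma / s


def _gauss_layer(ss: ScaleSpace, kp: Keypoint) -> np.ndarray:
    """Gaussian layer of the keypoint's octave nearest its refined scale."""
    _, _, sig_oct = _octave_coords(kp)
    idx = int(np.argmin(np.abs(ss.sigmas - sig_oct)))
    return ss.octaves[kp.octave][idx]


def _interp_peak(hist: np.ndarray, i: int) -> float:
    """Parabolic 3-point refinement of a histogram peak, in bin units."""
    n = len(hist)
    left, right = hist[(i - 1) % n], hist[(i + 1) % n]
    denom = left - 2.0 * hist[i] + right
    if abs(denom) < 1e-12:
        return float(i)
    return i + 0.5 * (left - right) / denom


def assign_orientations(
    kp: Keypoint,
    ss: ScaleSpace,
    n_bins: int = N_ORI_BINS,
    aux_ratio: float = AUX_PEAK_RATIO,
) -> list[OrientedKeypoint]:
    """Dominant gradient orientation(s) of a keypoint.

    Builds an ``n_bins`` histogram of gradient direction over a disc of
    radius ``3 * 1.5 sigma``, weighting each sample by its magnitude and a
    Gaussian of width ``1.5 sigma``.  Emits one oriented keypoint for the
    global peak and one per other bin exceeding ``aux_ratio`` of it; peak
    positions are refined parabolically, ties broken by lower bin index.
    A flat (all-zero histogram) patch emits nothing.
    """
    layer = _gauss_layer(ss, kp)
    h, w = layer.shape
    xc, yc, sig = _octave_coords(kp)
    sigma_w = ORI_SIGMA_FACTOR * sig
    radius = max(1, int(round(ORI_RADIUS_FACTOR * sigma_w)))

    r0 = max(1, int(round(yc)) - radius)
    r1 = min(h - 2, int(round(yc)) + radius)
    c0 = max(1, int(round(xc)) - radius)
    c1 = min(w - 2, int(round(xc)) + radius)
    if r0 > r1 or c0 > c1:
        return []

    patch = layer[r0 - 1 : r1 + 2, c0 - 1 : c1 + 2]
    dx = patch[1:-1, 2:] - patch[1:-1, :-2]
    dy = patch[2:, 1:-1] - patch[:-2, 1:-1]
    mag = np.hypot(dx, dy)
    ang = np.degrees(np.arctan2(dy, dx)) % 360.0

    rows = np.arange(r0, r1 + 1)[:, None] - yc
    cols = np.arange(c0, c1 + 1)[None, :] - xc
    dist2 = rows**2 + cols**2
    inside = dist2 <= radius**2
    weight = np.exp(-dist2 / (2.0 * sigma_w**2)) * inside

    # nearest-centre binning: bin b collects directions within half a bin
    # width of b * (360/n_bins), so a pure direction lands on its own centre
    bins = np.floor(ang * n_bins / 360.0 + 0.5).astype(int) % n_bins
    hist = np.bincount(bins.ravel(), weights=(mag * weight).ravel(), minlength=n_bins)

    peak = hist.max()
    if peak <= 0.0:
        logger.debug("flat patch at (%.1f, %.1f); no orientation", kp.x, kp.y)
        return []

    out: list[OrientedKeypoint] = []
    order = np.argsort(-hist, kind="stable")  # ties -> lower bin index first
    for i in order:
        v = hist[i]
        # auxiliary peaks must strictly exceed aux_ratio of the global peak
        if v < peak and v <= aux_ratio * peak:
            break
        prev_, next_ = hist[(i - 1) % n_bins], hist[(i + 1) % n_bins]
        if v < prev_ or v < next_:
            continue  # not a local maximum (shoulder of a stronger peak)
        theta = (_interp_peak(hist, int(i)) * 360.0 / n_bins) % 360.0
        out.append(OrientedKeypoint.from_keypoint(kp, theta))
    return out


def compute_descriptor(
    okp: OrientedKeypoint,
    ss: ScaleSpace,
    gauss_variance_6sigma: bool = False,
) -> Descriptor | None:
    """128-d gradient-histogram descriptor of an oriented keypoint.

    Samples the gradient field in a square window of side
    ``4 * 3 sigma * sqrt(2)`` rotated by ``-theta`` about the keypoint,
    distributing each sample over the 4x4 spatial cells and the 8 direction
    bins by trilinear interpolation.  Spatial weighting is a Gaussian of
    standard deviation equal to half the descriptor window width; pass
    ``gauss_variance_6sigma=True`` to instead use a Gaussian of variance
    ``6 sigma`` (an alternative reading of the weighting width).  The vector
    is L2-normalised, clamped at 0.2 per component, and renormalised.

    Returns None when the sampling window lies fully outside the image.
    """
    layer = _gauss_layer(ss, okp)
    h, w = layer.shape
    xc, yc, sig = _octave_coords(okp)
    cell = CELL_SIGMA_FACTOR * sig  # side of one of the 4x4 cells, px
    radius = int(round(cell * (N_CELLS + 1) / 2.0 * ROTATION_SLACK))
    radius = min(radius, int(math.hypot(h, w)))

    r0, r1 = int(round(yc)) - radius, int(round(yc)) + radius
    c0, c1 = int(round(xc)) - radius, int(round(xc)) + radius
    if r1 < 1 or c1 < 1 or r0 > h - 2 or c0 > w - 2:
        return None
    r0, r1 = max(1, r0), min(h - 2, r1)
    c0, c1 = max(1, c0), min(w - 2, c1)

    patch = layer[r0 - 1 : r1 + 2, c0 - 1 : c1 + 2]
    gdx = patch[1:-1, 2:] - patch[1:-1, :-2]
    gdy = patch[2:, 1:-1] - patch[:-2, 1:-1]
    mag = np.hypot(gdx, gdy)
    ang = np.degrees(np.arctan2(gdy, gdx)) % 360.0

    rows = np.arange(r0, r1 + 1)[:, None] - yc
    cols = np.arange(c0, c1 + 1)[None, :] - xc
    ct = math.cos(math.radians(okp.theta))
    st = math.sin(math.radians(okp.theta))
    # rotate sample offsets by -theta into the keypoint frame, in cell units
    u = (cols * ct + rows * st) / cell  # along-orientation axis
    v = (-cols * st + rows * ct) / cell

    rbin = v + N_CELLS / 2.0 - 0.5
    cbin = u + N_CELLS / 2.0 - 0.5
    obin = (ang - okp.theta) % 360.0 / (360.0 / N_DIR_BINS)

    if gauss_variance_6sigma:
        sigma_w_cells = math.sqrt(6.0 * sig) / cell
    else:
        sigma_w_cells = 0.5 * N_CELLS  # half the window width
    weight = np.exp(-(u**2 + v**2) / (2.0 * sigma_w_cells**2))

    valid = (rbin > -1) & (rbin < N_CELLS) & (cbin > -1) & (cbin < N_CELLS)
    if not valid.any():
        return None
    rb, cb, ob = rbin[valid], cbin[valid], obin[valid]
    wm = (weight * mag)[valid]

    hist = np.zeros((N_CELLS + 2, N_CELLS + 2, N_DIR_BINS))
    r_f = np.floor(rb).astype(int)
    c_f = np.floor(cb).astype(int)
    o_f = np.floor(ob).astype(int)
    dr, dc, do = rb - r_f, cb - c_f, ob - o_f
    for ir, wr in ((0, 1 - dr), (1, dr)):
        for ic, wc in ((0, 1 - dc), (1, dc)):
            for io, wo in ((0, 1 - do), (1, do)):
                np.add.at(
                    hist,
                    (r_f + ir + 1, c_f + ic + 1, (o_f + io) % N_DIR_BINS),
                    wm * wr * wc * wo,
                )
    vec = hist[1 : N_CELLS + 1, 1 : N_CELLS + 1, :].ravel()

    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        return None
    vec = vec / norm
    clipped = np.minimum(vec, CLAMP)
    norm2 = np.linalg.norm(clipped)
    if norm2 < 1e-12:
        return None
    return Descriptor(values=clipped / norm2, parent=okp, clipped=clipped)


def describe_keypoints(
    kps: list[Keypoint],
    ss: ScaleSpace,
    gauss_variance_6sigma: bool = False,
) -> tuple[list[OrientedKeypoint], np.ndarray]:
    """Orient and describe a keypoint list.

    Returns the oriented keypoints (auxiliary orientations included) and the
    matching (n, 128) descriptor matrix, rows aligned with the keypoints.
    """
    oriented: list[OrientedKeypoint] = []
    vecs: list[np.ndarray] = []
    for kp in kps:
        for okp in assign_orientations(kp, ss):
            d = compute_descriptor(okp, ss, gauss_variance_6sigma)
            if d is not None:
                oriented.append(okp)
                vecs.append(d.values)
    if not vecs:
        return [], np.zeros((0, DESCRIPTOR_LENGTH))
    return oriented, np.vstack(vecs)
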