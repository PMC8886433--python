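"""Canvas layout, backward warping and gradual-in/gradual-out blending.

The registered image is warped onto a canvas large enough to hold the
reference image and all four warped corners.  In the overlap the two images
are feathered: the reference weight ``d1`` ramps linearly from 1 (on its own
side of the overlap) to 0 (on the other image's side), ``d2 = 1 - d1``, so
``d1 + d2 = 1`` at every overlap pixel and the transition shows no seam.

Here ``H`` always maps registered-image (image 2) pixel coordinates into
reference-image (image 1) coordinates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import Homography33, apply_homography

logger = logging.getLogger(__name__)

__all__ = [
    "Canvas",
    "compute_canvas",
    "warp_image",
    "place_reference",
    "blend_gradual",
    "stitch_images",
]


@dataclass(frozen=True)
class Canvas:
    """Mosaic raster: ``origin`` is the reference-frame coordinate of pixel
    (0, 0); canvas pixel (X, Y) sits at reference coordinate (X, Y) + origin."""

    origin_x: int
    origin_y: int
    width: int
    height: int


def _corners(shape) -> np.ndarray:
    h, w = shape[:2]
    return np.array(
        [[0.0, 0.0], [w - 1.0, 0.0], [w - 1.0, h - 1.0], [0.0, h - 1.0]]
    )


def compute_canvas(img1, img2, H) -> Canvas:
    """Bounding box of the reference image and the warped corners of image 2."""
    warped = apply_homography(H, _corners(np.asarray(img2).shape))
    ref = _corners(np.asarray(img1).shape)
    allpts = np.vstack([ref, warped])
    lo = np.floor(allpts.min(axis=0)).astype(int)
    hi = np.ceil(allpts.max(axis=0)).astype(int)
    return Canvas(
        origin_x=int(lo[0]),
        origin_y=int(lo[1]),
        width=int(hi[0] - lo[0] + 1),
        height=int(hi[1] - lo[1] + 1),
    )


def warp_image(img2, H, canvas: Canvas) -> tuple[np.ndarray, np.ndarray]:
    """Backward-map image 2 onto the canvas with bilinear interpolation.

    Returns the warped image and a boolean mask of pixels whose source
    coordinate falls inside image 2.  Colour images are warped per channel.
    """
    img2 = np.asarray(img2, dtype=float)
    h2, w2 = img2.shape[:2]
    Hinv = (H if isinstance(H, Homography33) else Homography33(H)).inverse()

    X, Y = np.meshgrid(
        np.arange(canvas.width) + canvas.origin_x,
        np.arange(canvas.height) + canvas.origin_y,
    )
    pts = np.column_stack([X.ravel(), Y.ravel()]).astype(float)
    src = apply_homography(Hinv, pts)
    sx = src[:, 0].reshape(canvas.height, canvas.width)
    sy = src[:, 1].reshape(canvas.height, canvas.width)

    eps = 1e-9
    mask = (sx >= -eps) & (sx <= w2 - 1 + eps) & (sy >= -eps) & (sy <= h2 - 1 + eps)
    coords = np.array([sy.ravel(), sx.ravel()])

    def _map(channel):
        out = ndimage.map_coordinates(channel, coords, order=1, mode="constant", cval=0.0)
        return out.reshape(canvas.height, canvas.width)

    if img2.ndim == 2:
        warped = _map(img2) * mask
    else:
        warped = np.dstack([_map(img2[..., c]) for c in range(img2.shape[2])])
        warped *= mask[..., None]
    return warped, mask


def place_reference(img1, canvas: Canvas) -> tuple[np.ndarray, np.ndarray]:
    """Paste the reference image onto the canvas at its integer offset."""
    img1 = np.asarray(img1, dtype=float)
    h1, w1 = img1.shape[:2]
    shape = (canvas.height, canvas.width) + img1.shape[2:]
    out = np.zeros(shape)
    mask = np.zeros((canvas.height, canvas.width), dtype=bool)
    r0, c0 = -canvas.origin_y, -canvas.origin_x
    out[r0 : r0 + h1, c0 : c0 + w1] = img1
    mask[r0 : r0 + h1, c0 : c0 + w1] = True
    return out, mask


def _ramp_weights(
    mask1: np.ndarray, mask2: np.ndarray, overlap: np.ndarray
) -> np.ndarray:
    """Per-row (or per-column) linear feather weight d1 over the overlap.

    The ramp runs along the dominant displacement axis between the two
    footprints, from 1 at the image-1 side to 0 at the image-2 side:
    ``d1 = 1 - (x - x_start) / width`` for a left-to-right transition.
    """
    c1 = np.argwhere(mask1).mean(axis=0)
    c2 = np.argwhere(mask2).mean(axis=0)
    disp = c2 - c1  # (drow, dcol)
    axis = 1 if abs(disp[1]) >= abs(disp[0]) else 0
    reverse = disp[axis] < 0  # image 2 on the low-coordinate side

    d1 = np.zeros(overlap.shape)
    if axis == 1:
        lines = overlap
    else:
        lines = overlap.T
    w = np.zeros_like(d1.T if axis == 0 else d1)
    for i, line in enumerate(lines):
        cols = np.nonzero(line)[0]
        if len(cols) == 0:
            continue
        x0, x1 = cols[0], cols[-1]
        width = x1 - x0
        if width == 0:
            w[i, cols] = 0.5
        else:
            t = (cols - x0) / width
            w[i, cols] = (t if reverse else 1.0 - t)
    return w.T if axis == 0 else w


def _distance_weights(
    mask1: np.ndarray, mask2: np.ndarray, overlap: np.ndarray
) -> np.ndarray:
    """Distance-transform feather for irregular overlap shapes.

    ``d1 = dist_to_edge_of_img1 / (dist_to_edge_of_img1 + dist_to_edge_of_img2)``.
    """
    t1 = ndimage.distance_transform_edt(mask1)
    t2 = ndimage.distance_transform_edt(mask2)
    d1 = np.zeros(overlap.shape)
    s = t1 + t2
    np.divide(t1, s, out=d1, where=overlap & (s > 0))
    d1[overlap & (s <= 0)] = 0.5
    return d1


def blend_gradual(
    img1_on_canvas,
    warped2,
    mask1,
    mask2,
    ramp_mode: str = "axis",
    literal_halving: bool = False,
) -> np.ndarray:
    """Feathered composite of the two canvas-aligned images.

    Output equals image 1 where only it covers the canvas, image 2 where only
    it does, and ``d1 I1 + d2 I2`` with ``d1 + d2 = 1`` in the overlap, the
    weight ramping linearly across the overlap extent.

    Parameters
    ----------
    ramp_mode : "axis" or "distance"
        Linear per-row ramp along the dominant displacement axis (default) or
        a distance-transform weight for irregular overlaps.
    literal_halving : bool
        Apply an extra factor 1/2 to the overlap term.  This darkens the
        overlap and breaks the convexity that d1 + d2 = 1 implies; it exists
        only for fidelity experiments and is off by default.
    """
    I1 = np.asarray(img1_on_canvas, dtype=float)
    I2 = np.asarray(warped2, dtype=float)
    overlap = mask1 & mask2
    if not overlap.any():
        logger.warning("empty overlap: compositing without blending")
        d1 = np.zeros(mask1.shape)
    elif ramp_mode == "distance":
        d1 = _distance_weights(mask1, mask2, overlap)
    elif ramp_mode == "axis":
        d1 = _ramp_weights(mask1, mask2, overlap)
    else:
        raise ValueError(f"unknown ramp_mode {ramp_mode!r}")

    if I1.ndim == 3:
        d1e = d1[..., None]
        m1e, m2e, ove = mask1[..., None], mask2[..., None], overlap[..., None]
    else:
        d1e, m1e, m2e, ove = d1, mask1, mask2, overlap

    blended = d1e * I1 + (1.0 - d1e) * I2
    if literal_halving:
        blended = blended / 2.0
    out = np.where(ove, blended, np.where(m1e, I1, np.where(m2e, I2, 0.0)))
    return out


def stitch_images(img1, img2, H, ramp_mode: str = "axis",
                  literal_halving: bool = False) -> np.ndarray:
    """Warp image 2 by ``H`` (image-2 -> image-1 frame) and feather-blend."""
    canvas = compute_canvas(img1, img2, H)
    warped2, mask2 = warp_image(img2, H, canvas)
    placed1, mask1 = place_reference(img1, canvas)
    return blend_gradual(placed1, warped2, mask1, mask2, ramp_mode, literal_halving)
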