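"""Planar homography estimation and transfer-error computation.

A projective transform between two views of a (near-)planar scene is a 3x3
matrix ``H`` with the bottom-right entry fixed to 1, leaving 8 free
parameters.  A correspondence ``(x, y) -> (x', y')`` contributes two rows to
the direct linear transform (DLT) system ``X h = y``; four non-collinear
correspondences determine ``H`` exactly, more are solved in the least-squares
sense, minimising the algebraic residual ``||X h - y||^2``.

Coordinates are pixel units, x = column, y = row, 0-based.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Homography33",
    "apply_homography",
    "solve_dlt",
    "backprojection_error",
]

#: Number of free parameters of a plane projective transform (h33 fixed to 1).
N_HOMOGRAPHY_PARAMS = 8


class Homography33:
    """3x3 projective transform with the (3,3) entry normalised to 1.

    Parameters
    ----------
    matrix : (3, 3) array_like
        Any nonzero-scale representative; it is rescaled so ``H[2, 2] == 1``.

    Notes
    -----
    Fixing ``h33 = 1`` is singular when the true transform has ``h33 ~ 0``
    (a plane through the optical centre); such transforms do not arise
    between overlapping endoscope frames and are not supported.
    """

    __slots__ = ("matrix",)

    def __init__(self, matrix):
        M = np.asarray(matrix, dtype=float)
        if M.shape != (3, 3):
            raise ValueError(f"homography must be 3x3, got {M.shape}")
        if not np.isfinite(M).all():
            raise ValueError("homography entries must be finite")
        if abs(M[2, 2]) < 1e-12:
            raise ValueError("h33 is (near) zero; cannot normalise to h33=1")
        self.matrix = M / M[2, 2]

    @classmethod
    def identity(cls) -> "Homography33":
        return cls(np.eye(3))

    @property
    def params(self) -> np.ndarray:
        """The 8 free parameters (h11, h12, h13, h21, h22, h23, h31, h32)."""
        return self.matrix.ravel()[:8].copy()

    def inverse(self) -> "Homography33":
        return Homography33(np.linalg.inv(self.matrix))

    def __matmul__(self, other: "Homography33") -> "Homography33":
        return Homography33(self.matrix @ other.matrix)

    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"Homography33({np.array2string(self.matrix, precision=4)})"


def _as_matrix(H) -> np.ndarray:
    if isinstance(H, Homography33):
        return H.matrix
    return Homography33(H).matrix


def apply_homography(H, pts):
    """Map points through a homography: ``X' = H X`` with dehomogenisation.

    Parameters
    ----------
    H : Homography33 or (3, 3) array_like
    pts : (2,) or (n, 2) array_like
        Input points (x, y).

    Returns
    -------
    ndarray
        Mapped points, same shape as ``pts``.

    Raises
    ------
    ValueError
        If any point maps to infinity (zero homogeneous denominator).
    """
    M = _as_matrix(H)
    p = np.asarray(pts, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    hom = np.column_stack([p, np.ones(len(p))]) @ M.T
    w = hom[:, 2]
    if np.any(np.abs(w) < 1e-12):
        raise ValueError("point at infinity: h31*x + h32*y + h33 = 0")
    out = hom[:, :2] / w[:, None]
    return out[0] if single else out


def _normalising_transform(pts: np.ndarray) -> np.ndarray:
    """Hartley similarity: centroid to origin, mean distance sqrt(2)."""
    c = pts.mean(axis=0)
    d = np.sqrt(((pts - c) ** 2).sum(axis=1)).mean()
    s = np.sqrt(2.0) / d if d > 1e-12 else 1.0
    return np.array([[s, 0.0, -s * c[0]], [0.0, s, -s * c[1]], [0.0, 0.0, 1.0]])


def _dlt_system(src: np.ndarray, dst: np.ndarray):
    """Build the 2n x 8 design matrix X and right-hand side y."""
    x, y = src[:, 0], src[:, 1]
    xp, yp = dst[:, 0], dst[:, 1]
    n = len(src)
    X = np.zeros((2 * n, 8))
    X[0::2, 0] = x
    X[0::2, 1] = y
    X[0::2, 2] = 1.0
    X[0::2, 6] = -xp * x
    X[0::2, 7] = -xp * y
    X[1::2, 3] = x
    X[1::2, 4] = y
    X[1::2, 5] = 1.0
    X[1::2, 6] = -yp * x
    X[1::2, 7] = -yp * y
    rhs = np.empty(2 * n)
    rhs[0::2] = xp
    rhs[1::2] = yp
    return X, rhs


def solve_dlt(src, dst, normalize: bool = True) -> Homography33:
    """Estimate the homography mapping ``src`` points onto ``dst`` points.

    Builds the 2n x 8 DLT system and solves it by least squares.  For four
    non-collinear pairs the solution is exact; for more, it minimises
    ``||X h - y||^2`` (equal to the normal-equation solution
    ``(X^T X)^-1 X^T y`` whenever ``X^T X`` is well conditioned).

    Parameters
    ----------
    src, dst : (n, 2) array_like, n >= 4
        Corresponding points; ``H`` maps ``src -> dst``.
    normalize : bool
        Apply Hartley coordinate normalisation internally (default).  The raw
        unnormalised system is numerically fragile at image-scale
        coordinates; switch off only to reproduce the plain normal-equation
        path.

    Raises
    ------
    ValueError
        Fewer than 4 pairs, or a degenerate (rank-deficient) configuration
        such as collinear points.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("src and dst must both be (n, 2) point arrays")
    if len(src) < 4:
        raise ValueError(f"need >= 4 correspondences, got {len(src)}")
    if not (np.isfinite(src).all() and np.isfinite(dst).all()):
        raise ValueError("correspondences must be finite")

    if normalize:
        Ts = _normalising_transform(src)
        Td = _normalising_transform(dst)
        src_n = apply_homography(Ts, src)
        dst_n = apply_homography(Td, dst)
    else:
        Ts = Td = np.eye(3)
        src_n, dst_n = src, dst

    X, rhs = _dlt_system(src_n, dst_n)
    h, _, rank, _ = np.linalg.lstsq(X, rhs, rcond=None)
    if rank < 8:
        raise ValueError(
            "degenerate correspondence set (rank "
            f"{rank} < 8): points are collinear or coincident"
        )
    Hn = np.append(h, 1.0).reshape(3, 3)
    M = np.linalg.inv(Td) @ Hn @ Ts
    return Homography33(M)


def backprojection_error(H, src, dst):
    """Squared transfer distances and their sum under ``H``.

    For each pair, ``d_v^2 = ||(x', y') - H(x, y)||^2``; the total ``E`` is
    the sum over pairs — the quantity the least-squares refit minimises over
    the inlier set.

    Returns
    -------
    d2 : (n,) ndarray
        Per-pair squared transfer distance.
    E : float
        Sum of ``d2``.
    """
    src = np.atleast_2d(np.asarray(src, dtype=float))
    dst = np.atleast_2d(np.asarray(dst, dtype=float))
    mapped = apply_homography(H, src)
    d2 = ((dst - mapped) ** 2).sum(axis=1)
    return d2, float(d2.sum())
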