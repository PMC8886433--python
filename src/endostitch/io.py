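"""Readers and writers: images, homographies, match tables, reports.

Images (PNG/TIFF/JPEG, 8- or 16-bit, gray or RGB) are normalised to [0, 1]
floats on read; the original bit depth is remembered so writes round-trip.
Homographies serialise as a 3-line whitespace-delimited text file, match
sets as TSV, pipeline reports as JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import Homography33

__all__ = [
    "LoadedImage",
    "read_image",
    "write_image",
    "read_homography",
    "write_homography",
    "write_matches_tsv",
    "write_report",
]


@dataclass
class LoadedImage:
    """Float image in [0, 1] plus what is needed to write it back."""

    data: np.ndarray  # (h, w) or (h, w, 3) float in [0, 1]
    dtype: np.dtype  # original integer dtype

    @property
    def gray(self) -> np.ndarray:
        """Rec. 601 luminance (detection runs on this; colour kept for blending)."""
        if self.data.ndim == 2:
            return self.data
        d = self.data
        return d[..., 0] * 0.299 + d[..., 1] * 0.587 + d[..., 2] * 0.114


def read_image(path: str | Path) -> LoadedImage:
    """Read a PNG/TIFF/JPEG image, normalising intensities to [0, 1]."""
    path = Path(path)
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise ValueError(f"cannot read image {path} ({path.suffix or 'no suffix'}): {exc}")
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]  # drop alpha
    if arr.ndim not in (2, 3):
        raise ValueError(f"unsupported image shape {arr.shape} in {path}")
    if np.issubdtype(arr.dtype, np.integer):
        info = np.iinfo(arr.dtype)
        data = arr.astype(float) / info.max
        dtype = arr.dtype
    else:
        data = np.clip(arr.astype(float), 0.0, 1.0)
        dtype = np.dtype(np.uint8)
    return LoadedImage(data=data, dtype=np.dtype(dtype))


def write_image(path: str | Path, image: LoadedImage | np.ndarray,
                dtype: np.dtype | None = None) -> None:
    """Write a [0, 1] float image, restoring the original bit depth."""
    if isinstance(image, LoadedImage):
        data, dtype = image.data, image.dtype
    else:
        data = np.asarray(image, dtype=float)
        dtype = np.dtype(dtype or np.uint8)
    info = np.iinfo(dtype)
    scaled = np.round(np.clip(data, 0.0, 1.0) * info.max).astype(dtype)
    iio.imwrite(Path(path), scaled)


def write_homography(path: str | Path, H: Homography33) -> None:
    """3 rows x 3 columns, whitespace-delimited, row-major."""
    np.savetxt(path, H.matrix, fmt="%.12g")


def read_homography(path: str | Path) -> Homography33:
    M = np.loadtxt(path)
    return Homography33(M)


def write_matches_tsv(path: str | Path, rows: list[dict]) -> None:
    """Match dump: one row per candidate with its cascade fate.

    Columns: p_idx, q_idx, x1, y1, x2, y2, d1, d2, R, stage_kept — where
    stage_kept is the last stage the pair survived
    (nn / ratio / cross / ransac).
    """
    cols = ["p_idx", "q_idx", "x1", "y1", "x2", "y2", "d1", "d2", "R", "stage_kept"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in rows:
            fh.write("\t".join(
                f"{r[c]:.6g}" if isinstance(r[c], float) else str(r[c]) for c in cols
            ) + "\n")


def write_report(path: str | Path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
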