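"""Frame, mask and centroid I/O.

Images are held in memory as 2-D float arrays with intensities in [0, 1]
(``GrayImage``); segmentations as 2-D uint8 arrays of {0, 1}
(``BinaryMask``).  Coordinates are 0-based ``(row, col)`` with row
increasing downward, matching array indexing.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "read_image",
    "read_mask",
    "write_mask",
    "write_image",
    "write_centroids",
    "read_centroids",
    "write_metrics_report",
]

# Rec. 601 luma weights, shared with preprocess.to_grayscale.
_LUMA = np.array([0.299, 0.587, 0.114])


def _validate_gray(pixels: np.ndarray) -> np.ndarray:
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.shape[0] < 3 or pixels.shape[1] < 3:
        raise ValueError(
            f"expected a 2-D image of at least 3x3 pixels, got shape {pixels.shape}"
        )
    return pixels


def read_image(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF frame as a grayscale float image in [0, 1].

    8-bit input is divided by 255, 16-bit by 65535.  Three-channel input is
    collapsed to luminance (0.299 R + 0.587 G + 0.114 B).
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if raw.size == 0:
        raise ValueError(f"zero-sized image: {path}")
    if raw.dtype == np.uint8:
        scale = 255.0
    elif raw.dtype == np.uint16:
        scale = 65535.0
    else:
        raise ValueError(f"unsupported image dtype {raw.dtype} in {path}")
    pixels = raw.astype(float) / scale
    if pixels.ndim == 3:
        if pixels.shape[2] == 4:  # drop alpha
            pixels = pixels[:, :, :3]
        if pixels.shape[2] != 3:
            raise ValueError(
                f"expected 1 or 3 channels, got {pixels.shape[2]} in {path}"
            )
        pixels = pixels @ _LUMA
    return _validate_gray(pixels)


def write_image(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] grayscale image as 8-bit PNG (lossy to 1/255)."""
    image = _validate_gray(image)
    data = np.clip(np.rint(image * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary mask PNG; any nonzero pixel counts as foreground."""
    path = Path(path)
    try:
        raw = iio.imread(path)
    except (OSError, ValueError) as exc:
        raise OSError(f"cannot read mask file {path}: {exc}") from exc
    if raw.ndim == 3:
        raw = raw[:, :, 0]
    return (raw > 0).astype(np.uint8)


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a {0, 1} mask as an 8-bit PNG with values {0, 255}.

    The round trip ``read_mask(write_mask(m))`` is bit-exact.
    """
    mask = np.asarray(mask)
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask values must be exactly 0 or 1")
    iio.imwrite(Path(path), (mask.astype(np.uint8) * 255))


def write_centroids(centroids: list[tuple[float, float]], path: str | Path) -> None:
    """Write centroids as CSV with header ``id,row,col`` (0-based coords)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "row", "col"])
        for k, (row, col) in enumerate(centroids, start=1):
            writer.writerow([k, float(row), float(col)])


def read_centroids(path: str | Path) -> list[tuple[float, float]]:
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        return [(float(r["row"]), float(r["col"])) for r in reader]


def write_metrics_report(report: dict, path: str | Path) -> None:
    """Write an evaluation report as JSON (NaN encoded as null)."""

    def _clean(obj):
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, (float, np.floating)):
            return None if np.isnan(obj) else float(obj)
        if isinstance(obj, (int, np.integer)):
            return int(obj)
        return obj

    with open(path, "w") as fh:
        json.dump(_clean(report), fh, indent=2)
        fh.write("\n")
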