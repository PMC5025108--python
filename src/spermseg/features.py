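"""Head localisation: connected regions, border rejection, centroids.

The pulse mask is partitioned into maximal connected components
(8-connectivity by default, so anti-aliased blob edges stay whole), regions
touching a border band are discarded (partial heads at the frame edge would
yield misleading centroids), and the arithmetic mean of each surviving
region's pixel coordinates is reported as a sperm-head location.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Region",
    "label_regions",
    "filter_border",
    "centroids",
    "regions_to_mask",
    "match_detections",
]

_STRUCTS = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


@dataclass
class Region:
    """One labelled connected component of the segmentation mask."""

    label: int
    rows: np.ndarray
    cols: np.ndarray

    @property
    def area(self) -> int:
        return self.rows.size

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        """(row_min, col_min, row_max, col_max), inclusive."""
        return (
            int(self.rows.min()),
            int(self.cols.min()),
            int(self.rows.max()),
            int(self.cols.max()),
        )


def label_regions(mask: np.ndarray, connectivity: int = 8) -> list[Region]:
    """Label maximal connected foreground components (labels 1..K).

    The regions partition the foreground exactly: every 1-pixel belongs to
    one and only one region.
    """
    if connectivity not in _STRUCTS:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask)
    labelled, n = ndimage.label(mask != 0, structure=_STRUCTS[connectivity])
    regions = []
    for lab in range(1, n + 1):
        rows, cols = np.nonzero(labelled == lab)
        regions.append(Region(label=lab, rows=rows, cols=cols))
    return regions


def filter_border(
    regions: list[Region], shape: tuple[int, int], margin: int = 1
) -> list[Region]:
    """Drop any region with a pixel inside the ``margin``-wide border band.

    Idempotent; ``margin=0`` keeps everything.
    """
    if margin < 0:
        raise ValueError(f"margin must be >= 0, got {margin}")
    if margin == 0:
        return list(regions)
    h, w = shape
    kept = []
    for reg in regions:
        r0, c0, r1, c1 = reg.bbox
        if r0 >= margin and c0 >= margin and r1 < h - margin and c1 < w - margin:
            kept.append(reg)
    return kept


def centroids(regions: list[Region]) -> list[tuple[float, float]]:
    """Mean (row, col) of each region's pixels — the head locations."""
    return [reg.centroid for reg in regions]


def regions_to_mask(regions: list[Region], shape: tuple[int, int]) -> np.ndarray:
    """Render a region list back into a {0, 1} mask."""
    mask = np.zeros(shape, dtype=np.uint8)
    for reg in regions:
        mask[reg.rows, reg.cols] = 1
    return mask


def match_detections(
    predicted: list[tuple[float, float]],
    truth: list[tuple[float, float]],
    radius: float,
) -> tuple[int, int, int]:
    """Greedy one-to-one nearest matching within ``radius``.

    Candidate pairs are taken in order of increasing distance; ties are
    broken by row-major order of the truth point, then of the prediction.
    Returns (matched, missed, spurious) with matched + missed = len(truth)
    and matched + spurious = len(predicted).
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    truth_order = sorted(range(len(truth)), key=lambda i: truth[i])
    pred_order = sorted(range(len(predicted)), key=lambda j: predicted[j])
    pairs = []
    for rank_t, i in enumerate(truth_order):
        for rank_p, j in enumerate(pred_order):
            d = np.hypot(
                truth[i][0] - predicted[j][0], truth[i][1] - predicted[j][1]
            )
            if d <= radius:
                pairs.append((d, rank_t, rank_p, i, j))
    pairs.sort()
    used_t: set[int] = set()
    used_p: set[int] = set()
    matched = 0
    for _, _, _, i, j in pairs:
        if i in used_t or j in used_p:
            continue
        used_t.add(i)
        used_p.add(j)
        matched += 1
    return matched, len(truth) - matched, len(predicted) - matched
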