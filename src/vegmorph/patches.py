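"""Vegetation patch statistics.

A *patch* is a connected component of vegetation (foreground) pixels;
8-connectivity is the default, matching the 3×3-neighbourhood rule used
for the pixel graphs.  Per image, the reported size is the arithmetic
mean pixel count over all patches — the summary whose abrupt jump along
a rainfall (or cover) gradient marks the percolation-like coalescence
of many small patches into one spanning labyrinth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .segmentation import BinaryPattern

__all__ = [
    "PatchSizeSummary",
    "label_patches",
    "patch_size_summary",
    "patch_size_vs_driver",
]

_STRUCTURES = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
    8: np.ones((3, 3), dtype=bool),
}


@dataclass(frozen=True)
class PatchSizeSummary:
    """Per-patch pixel counts for one image.

    ``mean_size`` is None (not 0) for a pattern with no vegetation.
    """

    sizes: np.ndarray
    connectivity: int = 8

    @property
    def n_patches(self) -> int:
        return len(self.sizes)

    @property
    def total_pixels(self) -> int:
        return int(self.sizes.sum()) if len(self.sizes) else 0

    @property
    def mean_size(self) -> Optional[float]:
        if len(self.sizes) == 0:
            return None
        return float(self.sizes.mean())


def label_patches(pattern: BinaryPattern, connectivity: int = 8) -> np.ndarray:
    """Label foreground connected components; background = 0.

    Labels are assigned in raster-scan order of each component's first
    pixel, so the labelling is deterministic.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    labels, _ = ndimage.label(pattern.mask, structure=_STRUCTURES[connectivity])
    return labels


def patch_size_summary(pattern: BinaryPattern, connectivity: int = 8) -> PatchSizeSummary:
    """Pixel counts of every vegetation patch in a pattern."""
    labels = label_patches(pattern, connectivity)
    n = labels.max()
    if n == 0:
        sizes = np.empty(0, dtype=np.int64)
    else:
        sizes = np.bincount(labels.ravel())[1:].astype(np.int64)
    return PatchSizeSummary(sizes=sizes, connectivity=connectivity)


def patch_size_vs_driver(
    summaries: Sequence[PatchSizeSummary],
    drivers: Sequence[float],
) -> pd.DataFrame:
    """Tidy table of mean patch size against an environmental driver.

    One row per image, sorted by driver value (rainfall, cover fraction,
    …); no fitting is performed.
    """
    if len(summaries) != len(drivers):
        raise ValueError(
            f"got {len(summaries)} summaries but {len(drivers)} driver values"
        )
    df = pd.DataFrame(
        {
            "driver": np.asarray(drivers, dtype=float),
            "n_patches": [s.n_patches for s in summaries],
            "mean_size_px": [s.mean_size for s in summaries],
            "total_foreground_px": [s.total_pixels for s in summaries],
        }
    )
    return df.sort_values("driver", kind="stable").reset_index(drop=True)
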