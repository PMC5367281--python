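"""Readers and writers for rasters, masks and result tables.

Images go through imageio/Pillow; numeric grids and all result tables
are plain CSV so every artifact stays text-inspectable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .euler import EulerFeatureVector
from .morphospace import Embedding
from .patches import PatchSizeSummary
from .segmentation import BinaryPattern, BiomassGrid, GrayImage, rgb_to_gray

__all__ = [
    "read_gray_image",
    "read_biomass_csv",
    "read_mask",
    "write_mask_png",
    "write_mask_csv",
    "write_feature_table",
    "read_feature_table",
    "write_embedding",
    "write_patch_table",
    "write_manifest",
]

PathLike = Union[str, Path]


def read_gray_image(path: PathLike, provenance: str = "satellite") -> GrayImage:
    """Load a PNG/TIFF/JPEG image as a [0,1] grayscale raster.

    RGB(A) inputs are converted by luminance; integer images are scaled
    by their dtype maximum.
    """
    arr = np.asarray(iio.imread(path))
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(float) / np.iinfo(arr.dtype).max
    else:
        arr = arr.astype(float)
    if arr.ndim == 3:
        if arr.shape[2] >= 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            arr = rgb_to_gray(arr)
        else:
            arr = arr[:, :, 0]
    return GrayImage(np.clip(arr, 0.0, 1.0), provenance)


def read_biomass_csv(path: PathLike, cell_size_m: float = 2.0) -> BiomassGrid:
    """Load a plain numeric CSV grid of biomass values (g m⁻²)."""
    values = np.loadtxt(path, delimiter=",", ndmin=2)
    return BiomassGrid(values, cell_size_m=cell_size_m)


def read_mask(path: PathLike) -> BinaryPattern:
    """Load a binary mask from a 0/1 CSV or an image file (nonzero = foreground)."""
    path = Path(path)
    if path.suffix.lower() in {".csv", ".txt"}:
        values = np.loadtxt(path, delimiter=",", ndmin=2)
        if not np.isin(values, (0, 1)).all():
            raise ValueError(f"{path} is not a strictly 0/1 mask")
        return BinaryPattern(values.astype(bool))
    arr = np.asarray(iio.imread(path))
    if arr.ndim == 3:
        arr = arr[:, :, :3].max(axis=2)
    return BinaryPattern(arr > 0)


def write_mask_png(pattern: BinaryPattern, path: PathLike) -> None:
    """Write a mask as an 8-bit PNG: foreground white (255), background black."""
    iio.imwrite(Path(path), (pattern.mask.astype(np.uint8) * 255))


def write_mask_csv(pattern: BinaryPattern, path: PathLike) -> None:
    np.savetxt(Path(path), pattern.mask.astype(int), fmt="%d", delimiter=",")


def write_feature_table(
    vectors: Sequence[EulerFeatureVector],
    path: PathLike,
) -> pd.DataFrame:
    """One row per image: id, polarity, chi_1 … chi_n (bit-exact integers)."""
    rows = []
    for i, v in enumerate(vectors):
        row = {"id": v.pattern_id or f"img_{i}", "polarity": v.polarity}
        row.update({f"chi_{k + 1}": int(c) for k, c in enumerate(v.chi)})
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, index=False)
    return df


def read_feature_table(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    chi_cols = [c for c in df.columns if c.startswith("chi_")]
    if not chi_cols:
        raise ValueError(f"{path} has no chi_* feature columns")
    return df


def write_embedding(
    embedding: Embedding,
    scores_path: PathLike,
    variance_path: Optional[PathLike] = None,
    ids: Optional[Sequence[str]] = None,
) -> None:
    """Write PCA scores (id, label, PC1…PCk) and explained-variance ratios."""
    n, k = embedding.scores.shape
    df = pd.DataFrame(embedding.scores, columns=[f"PC{i + 1}" for i in range(k)])
    df.insert(0, "id", list(ids) if ids is not None else [f"img_{i}" for i in range(n)])
    if embedding.labels is not None:
        df.insert(1, "label", embedding.labels)
    df.to_csv(scores_path, index=False)
    if variance_path is not None:
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(embedding.explained_variance_ratio))],
                "explained_variance_ratio": embedding.explained_variance_ratio,
            }
        ).to_csv(variance_path, index=False)


def write_patch_table(
    summaries: Sequence[PatchSizeSummary],
    ids: Sequence[str],
    path: PathLike,
    drivers: Optional[Sequence[float]] = None,
) -> pd.DataFrame:
    """Per-image patch statistics; individual sizes stored as a quoted list."""
    if len(ids) != len(summaries):
        raise ValueError("ids and summaries must have equal length")
    rows = []
    for i, (sid, s) in enumerate(zip(ids, summaries)):
        rows.append(
            {
                "id": sid,
                "driver": None if drivers is None else drivers[i],
                "n_patches": s.n_patches,
                "mean_size_px": s.mean_size,
                "sizes": json.dumps([int(x) for x in s.sizes]),
            }
        )
    df = pd.DataFrame(rows)
    if drivers is None:
        df = df.drop(columns=["driver"])
    df.to_csv(path, index=False)
    return df


def write_manifest(path: PathLike, config: dict) -> None:
    """Record run parameters and library versions next to each output."""
    import scipy
    import skimage

    manifest = {
        "config": config,
        "versions": {
            "vegmorph": _package_version(),
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))


def _package_version() -> str:
    from . import __version__

    return __version__
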