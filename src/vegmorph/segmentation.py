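"""Segmentation of raw vegetation imagery into binary patterns.

Two recipes are supported, mirroring the two image sources used in
dryland-pattern morphometry:

* **Model output** — gridded biomass (g m⁻²) from an ecohydrological
  simulation is thresholded at a fixed biomass value, rescaled with
  bilinear interpolation, cropped to a square analysis window and
  re-binarized.
* **Satellite chips** — a grayscale (or RGB, converted by luminance)
  image is cropped, downscaled to the analysis window and thresholded on
  pixel intensity (Otsu by default) to delineate vegetated patches.

The output convention throughout is: foreground (``True``) = vegetation
patches, background (``False``) = bare-ground interpatches.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Tuple, Union

import numpy as np
from skimage.filters import threshold_otsu
from skimage.transform import resize

__all__ = [
    "BiomassGrid",
    "GrayImage",
    "BinaryPattern",
    "SegmentationConfig",
    "binarize_biomass",
    "rescale_bilinear",
    "crop_window",
    "binarize_intensity",
    "segment_model_image",
    "segment_satellite_image",
    "rgb_to_gray",
]

# BT.709 luminance weights for RGB → grayscale conversion.
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass(frozen=True)
class BiomassGrid:
    """A 2-D raster of vegetation biomass, in grams per square metre.

    Parameters
    ----------
    values
        Non-negative finite biomass per cell.
    cell_size_m
        Ground footprint of one (square) cell edge, metres.
    """

    values: np.ndarray
    cell_size_m: float = 2.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError(f"biomass grid must be 2-D and at least 2x2, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("biomass grid contains non-finite values")
        if np.any(v < 0):
            raise ValueError("biomass grid contains negative values")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class GrayImage:
    """A 2-D grayscale raster with intensities scaled to [0, 1]."""

    values: np.ndarray
    provenance: Literal["model-render", "satellite", "synthetic"] = "synthetic"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError(f"gray image must be a non-empty 2-D raster, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("gray image contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("gray image intensities must lie in [0, 1]")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryPattern:
    """A binary vegetation pattern.

    ``True`` pixels are vegetation (foreground, rendered white);
    ``False`` pixels are bare ground (background, rendered black).
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != bool:
            if not np.isin(m, (0, 1)).all():
                raise ValueError("mask must be boolean or strictly 0/1 valued")
            m = m.astype(bool)
        if m.ndim != 2 or m.size == 0:
            raise ValueError(f"mask must be a non-empty 2-D raster, got shape {m.shape}")
        object.__setattr__(self, "mask", m)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.mask.shape

    @property
    def cover_fraction(self) -> float:
        """Fraction of pixels that are vegetation."""
        return float(self.mask.mean())

    def complement(self) -> "BinaryPattern":
        return BinaryPattern(~self.mask)


@dataclass(frozen=True)
class SegmentationConfig:
    """Parameters of the two segmentation recipes.

    Defaults follow the published workflow: 5 g m⁻² biomass threshold,
    ×0.17 bilinear rescale, 50×50 analysis window, 350×350 satellite
    crop, Otsu intensity threshold with dark pixels read as vegetation
    (dry-season canopies are darker than bare soil).
    """

    biomass_threshold: float = 5.0
    rescale_factor: float = 0.17
    crop_size: int = 50
    satellite_crop_size: int = 350
    intensity_method: Literal["otsu", "fixed"] = "otsu"
    fixed_threshold: float = 0.5
    polarity_hint: Literal["bright-is-vegetation", "dark-is-vegetation"] = "dark-is-vegetation"
    # Nearest-neighbour upsample applied to a raw biomass grid before the
    # bilinear rescale, so that a 100x100 grid survives the x0.17 reduction
    # with room for a 50x50 window (100*4*0.17 = 68 px).
    grid_upsample: int = 4
    crop_origin: Union[Tuple[int, int], None] = None  # None = centered


def rgb_to_gray(rgb: np.ndarray) -> np.ndarray:
    """Convert an (H, W, 3) RGB array in [0, 1] to luminance grayscale."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("expected an (H, W, 3) RGB array")
    return np.clip(rgb @ _LUMA, 0.0, 1.0)


def binarize_biomass(grid: BiomassGrid, threshold: float = 5.0) -> BinaryPattern:
    """Threshold a biomass grid: cells with biomass >= threshold become vegetation.

    The inclusive boundary rule keeps the all-equal grid deterministic.
    """
    if threshold <= 0:
        raise ValueError("biomass threshold must be positive")
    return BinaryPattern(grid.values >= threshold)


def rescale_bilinear(image: GrayImage, factor: float) -> GrayImage:
    """Rescale an image by a multiplicative factor with bilinear interpolation.

    Output dimensions are ``round(dim * factor)`` per axis.
    """
    if factor <= 0:
        raise ValueError("rescale factor must be positive")
    h, w = image.shape
    out_shape = (int(round(h * factor)), int(round(w * factor)))
    if out_shape[0] < 1 or out_shape[1] < 1:
        raise ValueError(f"factor {factor} maps {image.shape} to empty output {out_shape}")
    if factor == 1.0:
        return GrayImage(image.values.copy(), image.provenance)
    out = resize(
        image.values,
        out_shape,
        order=1,
        mode="edge",
        anti_aliasing=False,
        preserve_range=True,
    )
    return GrayImage(np.clip(out, 0.0, 1.0), image.provenance)


def crop_window(image, origin: Tuple[int, int], size: Tuple[int, int]):
    """Crop a (row, col) window; 0-based, half-open coordinates.

    Works on :class:`GrayImage` and :class:`BinaryPattern` alike and
    returns the same type.
    """
    r0, c0 = origin
    h, w = size
    if h < 1 or w < 1:
        raise ValueError("crop size must be at least 1x1")
    if isinstance(image, GrayImage):
        arr = image.values
    elif isinstance(image, BinaryPattern):
        arr = image.mask
    else:
        raise TypeError(f"cannot crop object of type {type(image).__name__}")
    H, W = arr.shape
    if r0 < 0 or c0 < 0 or r0 + h > H or c0 + w > W:
        raise ValueError(
            f"crop window rows [{r0},{r0 + h}) cols [{c0},{c0 + w}) "
            f"exceeds image of shape {(H, W)}"
        )
    sub = arr[r0 : r0 + h, c0 : c0 + w].copy()
    if isinstance(image, GrayImage):
        return GrayImage(sub, image.provenance)
    return BinaryPattern(sub)


def _centered_origin(shape: Tuple[int, int], size: Tuple[int, int]) -> Tuple[int, int]:
    return ((shape[0] - size[0]) // 2, (shape[1] - size[1]) // 2)


def binarize_intensity(
    image: GrayImage,
    method: Literal["otsu", "fixed"] = "otsu",
    threshold: float = 0.5,
    polarity_hint: Literal["bright-is-vegetation", "dark-is-vegetation"] = "dark-is-vegetation",
) -> BinaryPattern:
    """Threshold pixel intensities to delineate vegetated patches.

    With ``bright-is-vegetation`` pixels strictly above the threshold are
    vegetation; with ``dark-is-vegetation`` the mask is the exact
    complement (pixels <= threshold). Otsu's method picks the threshold
    from the intensity histogram; it is undefined on a constant image.
    """
    v = image.values
    if method == "otsu":
        if v.min() == v.max():
            raise ValueError("Otsu threshold undefined for a constant image")
        t = float(threshold_otsu(v))
    elif method == "fixed":
        if not (0.0 < threshold < 1.0):
            raise ValueError("fixed intensity threshold must lie strictly in (0, 1)")
        t = threshold
    else:
        raise ValueError(f"unknown intensity method {method!r}")
    bright = v > t
    if polarity_hint == "bright-is-vegetation":
        return BinaryPattern(bright)
    if polarity_hint == "dark-is-vegetation":
        return BinaryPattern(~bright)
    raise ValueError(f"unknown polarity hint {polarity_hint!r}")


def _nearest_upsample(values: np.ndarray, factor: int) -> np.ndarray:
    return np.repeat(np.repeat(values, factor, axis=0), factor, axis=1)


def segment_model_image(
    source: Union[BiomassGrid, GrayImage],
    config: SegmentationConfig = SegmentationConfig(),
) -> BinaryPattern:
    """Segment model output into a binary analysis window.

    Pipeline: biomass threshold → bilinear rescale (×0.17) → crop
    (50×50) → re-binarize at 0.5 on the interpolated values. A raw
    biomass grid is first nearest-neighbour upsampled (``grid_upsample``)
    so the rescaled raster still contains the analysis window.
    """
    if isinstance(source, BiomassGrid):
        binary = binarize_biomass(source, config.biomass_threshold)
        raw = _nearest_upsample(binary.mask.astype(float), config.grid_upsample)
        gray = GrayImage(raw, "model-render")
    elif isinstance(source, GrayImage):
        # A pre-rendered model image: threshold on intensity first
        # (bright = vegetated render), matching the biomass threshold step.
        gray = GrayImage((source.values > 0.5).astype(float), "model-render")
    else:
        raise TypeError("segment_model_image expects a BiomassGrid or GrayImage")

    scaled = rescale_bilinear(gray, config.rescale_factor)
    size = (config.crop_size, config.crop_size)
    if scaled.shape[0] < size[0] or scaled.shape[1] < size[1]:
        raise ValueError(
            f"rescaled image {scaled.shape} is smaller than the {size} analysis window; "
            "increase grid_upsample or rescale_factor"
        )
    origin = config.crop_origin or _centered_origin(scaled.shape, size)
    window = crop_window(scaled, origin, size)
    return BinaryPattern(window.values >= 0.5)


def segment_satellite_image(
    image: GrayImage,
    config: SegmentationConfig = SegmentationConfig(),
) -> BinaryPattern:
    """Segment a satellite chip into a binary analysis window.

    Pipeline: crop a ``satellite_crop_size`` square window → downscale to
    ``crop_size`` (bilinear) → intensity threshold (Otsu by default, dark
    pixels read as vegetation).
    """
    crop = config.satellite_crop_size
    if image.shape[0] < crop or image.shape[1] < crop:
        raise ValueError(
            f"satellite image {image.shape} is smaller than the required "
            f"{crop}x{crop} crop window"
        )
    origin = config.crop_origin or _centered_origin(image.shape, (crop, crop))
    window = crop_window(image, origin, (crop, crop))
    # Strong reductions (350 -> 50) need a smoothing prefilter, otherwise the
    # sparse bilinear sampling aliases fine patch structure.
    out = resize(
        window.values,
        (config.crop_size, config.crop_size),
        order=1,
        mode="edge",
        anti_aliasing=True,
        preserve_range=True,
    )
    small = GrayImage(np.clip(out, 0.0, 1.0), image.provenance)
    return binarize_intensity(
        small,
        method=config.intensity_method,
        threshold=config.fixed_threshold,
        polarity_hint=config.polarity_hint,
    )
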