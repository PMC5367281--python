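"""Seeded synthetic vegetation patterns.

Dryland vegetation self-organizes into a canonical morphology sequence
along increasing water availability: spots → labyrinths → gaps.  This
module emulates that sequence without any ecohydrological model, by
thresholding a smoothed Gaussian random field at a controlled cover
fraction: low cover yields isolated spots, ~50% cover yields reticulate
labyrinths, high cover yields a connected canopy with bare-ground gaps.
It also provides an idealized disk-lattice "spotted" pattern with an
analytic patch count, and tiny deterministic fixtures.

Every generator is a pure function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .segmentation import BinaryPattern

__all__ = [
    "PatternSpec",
    "smoothed_field_pattern",
    "disk_lattice_pattern",
    "fixture",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("full", "empty", "checkerboard", "half-plane", "single-pixel")


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of a smoothed-random-field pattern.

    ``cover_fraction`` is the exact foreground (vegetation) fraction;
    ``correlation_length_px`` sets the characteristic patch/gap scale
    (Gaussian smoothing sigma, in pixels).
    """

    shape: Tuple[int, int] = (50, 50)
    cover_fraction: float = 0.5
    correlation_length_px: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.cover_fraction < 1.0):
            raise ValueError("cover_fraction must lie strictly in (0, 1)")
        if self.correlation_length_px <= 0:
            raise ValueError("correlation_length_px must be positive")
        if self.shape[0] < 1 or self.shape[1] < 1:
            raise ValueError("shape must be at least 1x1")


def smoothed_field_pattern(spec: PatternSpec) -> BinaryPattern:
    """Threshold a periodically smoothed white-noise field at an exact cover quantile.

    The threshold is the k-th largest field value for k = round(cover·N),
    so the realized foreground fraction equals the requested cover up to
    one pixel in N — ties in a continuous field have probability zero.
    """
    rng = np.random.default_rng(spec.seed)
    noise = rng.standard_normal(spec.shape)
    field = ndimage.gaussian_filter(noise, sigma=spec.correlation_length_px, mode="wrap")
    n = field.size
    k = int(round(spec.cover_fraction * n))
    k = min(max(k, 1), n)
    flat = np.sort(field.ravel())[::-1]
    return BinaryPattern(field >= flat[k - 1])


def disk_lattice_pattern(
    shape: Tuple[int, int] = (50, 50),
    n: int = 3,
    radius: int = 2,
) -> BinaryPattern:
    """An n×n lattice of equal disks: an idealized spotted pattern.

    Guarantees exactly n² patches of identical pixel size under
    8-connectivity, which requires at least one full bare pixel between
    disks: lattice spacing must be ≥ 2·radius + 2.
    """
    if n < 1 or radius < 0:
        raise ValueError("need n >= 1 and radius >= 0")
    h, w = shape
    spacing = min(h, w) // n
    if spacing < 2 * radius + 2:
        raise ValueError(
            f"disks of radius {radius} at spacing {spacing} would touch or overlap "
            f"(need spacing >= {2 * radius + 2})"
        )
    centers = [(int((i + 0.5) * h / n), int((j + 0.5) * w / n)) for i in range(n) for j in range(n)]
    dy, dx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    stencil = dy**2 + dx**2 <= radius**2
    mask = np.zeros(shape, dtype=bool)
    for r0, c0 in centers:
        if r0 - radius < 0 or c0 - radius < 0 or r0 + radius >= h or c0 + radius >= w:
            raise ValueError("disk lattice does not fit inside the requested shape")
        mask[r0 - radius : r0 + radius + 1, c0 - radius : c0 + radius + 1] |= stencil
    return BinaryPattern(mask)


def fixture(name: str, shape: Tuple[int, int] = (50, 50)) -> BinaryPattern:
    """Deterministic named test patterns.

    full / empty — uniform masks; checkerboard — alternating pixels
    (⌈N/2⌉ foreground, all mutually diagonal-adjacent); half-plane —
    left half foreground; single-pixel — one foreground pixel at the
    center.
    """
    h, w = shape
    if name == "full":
        return BinaryPattern(np.ones(shape, dtype=bool))
    if name == "empty":
        return BinaryPattern(np.zeros(shape, dtype=bool))
    if name == "checkerboard":
        rr, cc = np.mgrid[0:h, 0:w]
        return BinaryPattern((rr + cc) % 2 == 0)
    if name == "half-plane":
        mask = np.zeros(shape, dtype=bool)
        mask[:, : w // 2] = True
        return BinaryPattern(mask)
    if name == "single-pixel":
        mask = np.zeros(shape, dtype=bool)
        mask[h // 2, w // 2] = True
        return BinaryPattern(mask)
    raise ValueError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
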