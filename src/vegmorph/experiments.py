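"""Desk-scale study designs on synthetic patterns.

Two self-contained numerical experiments reproduce, on seeded synthetic
data, the qualitative findings that motivate the method:

* :func:`morphospace_study` — three pattern classes (spots, labyrinths,
  gaps at cover 0.15 / 0.50 / 0.85) are embedded via background-polarity
  feature vectors and PCA; a correct implementation separates the
  classes into disjoint PC1 intervals with PC1 carrying essentially all
  variance.
* :func:`percolation_sweep` — mean vegetation patch size along a cover
  sweep jumps by over an order of magnitude across the coalescence
  transition, the regime change from several individual patches to a
  single spanning labyrinth.

The coalescence transition window is operationalized without free
parameters: its lower bracket is the last sweep step at which no
replicate contains a lattice-spanning patch (patterns are still
collections of individual patches), its upper bracket the first step at
which most replicates consist of a single patch (a continuous
labyrinth).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .euler import EulerFeatureVector, feature_vector
from .morphospace import Embedding, cluster_separation, feature_matrix, pca_embed
from .patches import label_patches, patch_size_summary
from .segmentation import BinaryPattern
from .synthetic import PatternSpec, smoothed_field_pattern

__all__ = [
    "MorphospaceStudy",
    "PercolationSweep",
    "morphospace_study",
    "percolation_sweep",
    "spans_lattice",
]

MORPHOLOGY_CLASSES = (("spots", 0.15), ("labyrinths", 0.50), ("gaps", 0.85))


@dataclass(frozen=True)
class MorphospaceStudy:
    vectors: List[EulerFeatureVector]
    labels: List[str]
    embedding: Embedding
    separation: pd.DataFrame

    @property
    def pc1_variance(self) -> float:
        return float(self.embedding.explained_variance_ratio[0])

    @property
    def all_disjoint(self) -> bool:
        return bool(self.separation["disjoint"].all())

    def mean_steepness(self, label: str) -> float:
        vals = [v.steepness for v, l in zip(self.vectors, self.labels) if l == label]
        return float(np.mean(vals))


def morphospace_study(
    base_seed: int = 0,
    n_per_class: int = 10,
    shape: Tuple[int, int] = (50, 50),
    correlation_length_px: float = 3.0,
    polarity: str = "background",
) -> MorphospaceStudy:
    """Generate the three-class pattern set and embed it in the morphospace.

    Replicate seeds are ``base_seed + 1000*class_index + i``.
    """
    vectors, labels = [], []
    for ci, (name, cover) in enumerate(MORPHOLOGY_CLASSES):
        for i in range(n_per_class):
            spec = PatternSpec(shape, cover, correlation_length_px,
                               seed=base_seed + 1000 * ci + i)
            pattern = smoothed_field_pattern(spec)
            vectors.append(feature_vector(pattern, polarity, pattern_id=f"{name}_{i}"))
            labels.append(name)
    matrix = feature_matrix(vectors, labels)
    embedding = pca_embed(matrix)
    separation = cluster_separation(embedding)
    return MorphospaceStudy(vectors=vectors, labels=labels,
                            embedding=embedding, separation=separation)


def spans_lattice(pattern: BinaryPattern) -> bool:
    """True if the largest vegetation patch touches all four image edges."""
    labels = label_patches(pattern)
    if labels.max() == 0:
        return False
    largest = int(np.argmax(np.bincount(labels.ravel())[1:])) + 1
    m = labels == largest
    return bool(m[0, :].any() and m[-1, :].any() and m[:, 0].any() and m[:, -1].any())


@dataclass(frozen=True)
class PercolationSweep:
    table: pd.DataFrame  # per cover: mean_size, mean_count, n_spanning, n_single
    onset_cover: float
    coalesced_cover: float
    jump_factor: float


def percolation_sweep(
    base_seed: int = 0,
    covers: np.ndarray | None = None,
    n_seeds: int = 5,
    shape: Tuple[int, int] = (50, 50),
    correlation_length_px: float = 1.5,
) -> PercolationSweep:
    """Mean patch size along a cover sweep, with the coalescence brackets.

    ``jump_factor`` is the ratio of mean patch size between the upper and
    lower transition brackets (see module docstring).
    """
    if covers is None:
        covers = np.arange(0.10, 0.901, 0.05)
    rows = []
    for ci, cover in enumerate(covers):
        sizes, counts, spanning, single = [], [], 0, 0
        for s in range(n_seeds):
            spec = PatternSpec(shape, float(cover), correlation_length_px,
                               seed=base_seed + 10 * ci + s)
            pattern = smoothed_field_pattern(spec)
            summary = patch_size_summary(pattern)
            sizes.append(summary.mean_size)
            counts.append(summary.n_patches)
            spanning += spans_lattice(pattern)
            single += summary.n_patches == 1
        rows.append(
            {
                "cover": float(cover),
                "mean_size_px": float(np.mean(sizes)),
                "mean_n_patches": float(np.mean(counts)),
                "n_spanning": spanning,
                "n_single_patch": single,
            }
        )
    table = pd.DataFrame(rows)

    no_span = table.index[table["n_spanning"] == 0]
    if len(no_span) == 0:
        raise RuntimeError("sweep never visits the individual-patch regime")
    below = int(no_span.max())
    majority = (n_seeds // 2) + 1
    coalesced = table.index[(table["n_single_patch"] >= majority) & (table.index > below)]
    if len(coalesced) == 0:
        raise RuntimeError("sweep never reaches the single-patch regime")
    above = int(coalesced.min())
    jump = table.loc[above, "mean_size_px"] / table.loc[below, "mean_size_px"]
    return PercolationSweep(
        table=table,
        onset_cover=float(table.loc[below, "cover"]),
        coalesced_cover=float(table.loc[above, "cover"]),
        jump_factor=float(jump),
    )
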