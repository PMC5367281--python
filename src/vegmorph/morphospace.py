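"""Pattern morphospace: PCA embedding of χ feature vectors.

All 20 features share units (Euler-characteristic counts), so the PCA
is performed on the column-centered covariance — no per-feature
standardization.  On both simulated and satellite-derived pattern sets
the first principal component captures essentially all the variance, so
pattern classes are read off PC1 score intervals; a small overlap
report quantifies their separation.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .euler import EulerFeatureVector

__all__ = [
    "Embedding",
    "feature_matrix",
    "pca_embed",
    "cluster_separation",
]


@dataclass(frozen=True)
class Embedding:
    """A PCA embedding of a feature matrix.

    ``scores`` are the centered data projected onto ``loadings`` (rows =
    images, columns = components); ``explained_variance_ratio`` covers
    the full spectrum and sums to 1.  Component signs are fixed so each
    loading vector's largest-magnitude entry is positive, making score
    files reproducible.
    """

    scores: np.ndarray
    loadings: np.ndarray  # (n_components, n_features)
    explained_variance_ratio: np.ndarray  # full spectrum
    column_means: np.ndarray
    labels: Optional[np.ndarray] = None

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def reconstruct(self) -> np.ndarray:
        """Inverse transform: scores × loadings + column means."""
        return self.scores @ self.loadings + self.column_means


def feature_matrix(
    vectors: Sequence[EulerFeatureVector],
    labels: Optional[Sequence] = None,
) -> pd.DataFrame:
    """Stack feature vectors into a tidy matrix (rows = images, cols = chi_k)."""
    if not vectors:
        raise ValueError("need at least one feature vector")
    n = len(vectors[0])
    if any(len(v) != n for v in vectors):
        raise ValueError("all feature vectors must have the same length")
    df = pd.DataFrame(
        np.vstack([v.chi for v in vectors]),
        columns=[f"chi_{k + 1}" for k in range(n)],
        index=[v.pattern_id or f"img_{i}" for i, v in enumerate(vectors)],
    )
    if labels is not None:
        if len(labels) != len(vectors):
            raise ValueError("labels length must match number of vectors")
        df.insert(0, "label", list(labels))
    return df


def _as_array(matrix) -> tuple[np.ndarray, Optional[np.ndarray]]:
    if isinstance(matrix, pd.DataFrame):
        labels = matrix["label"].to_numpy() if "label" in matrix.columns else None
        x = matrix.drop(columns=["label"], errors="ignore").to_numpy(dtype=float)
        return x, labels
    return np.asarray(matrix, dtype=float), None


def pca_embed(matrix, n_components: Optional[int] = None) -> Embedding:
    """Covariance PCA of a feature matrix.

    Deterministic up to the fixed sign convention; raises on a constant
    matrix, where no direction of variance exists.
    """
    x, labels = _as_array(matrix)
    n_rows, n_feat = x.shape
    if n_rows < 2:
        raise ValueError("PCA requires at least 2 rows")
    if np.isnan(x).any():
        raise ValueError("feature matrix contains missing values")
    means = x.mean(axis=0)
    xc = x - means
    if not np.any(np.abs(xc) > 0):
        raise ValueError("feature matrix is constant: zero variance, PCA undefined")

    max_rank = min(n_rows - 1, n_feat)
    if n_components is None:
        n_components = max_rank
    if not (1 <= n_components <= max_rank):
        raise ValueError(f"n_components must be in [1, {max_rank}], got {n_components}")

    # SVD of the centered data: principal axes = rows of vt,
    # component variances = s^2 / (n_rows - 1).
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    ratios = var / var.sum()

    # sign convention: largest-|.| loading entry positive
    flip = np.sign(vt[np.arange(len(vt)), np.argmax(np.abs(vt), axis=1)])
    flip[flip == 0] = 1.0
    vt = vt * flip[:, None]

    scores = xc @ vt[:n_components].T
    return Embedding(
        scores=scores,
        loadings=vt[:n_components],
        explained_variance_ratio=ratios,
        column_means=means,
        labels=labels,
    )


def cluster_separation(embedding: Embedding, labels: Optional[Sequence] = None) -> pd.DataFrame:
    """Pairwise PC1-interval overlap report for labelled pattern classes.

    For each pair of labels: whether the [min, max] PC1 score intervals
    are disjoint, and the signed gap between them (positive = separated
    by that margin; negative = overlapping by that amount).
    """
    if labels is None:
        labels = embedding.labels
    if labels is None:
        raise ValueError("labels must be supplied (none stored on the embedding)")
    labels = np.asarray(labels)
    if len(labels) != len(embedding.scores):
        raise ValueError("labels length must match number of embedded rows")
    pc1 = embedding.scores[:, 0]
    rows = []
    for a, b in combinations(pd.unique(labels), 2):
        ia, ib = pc1[labels == a], pc1[labels == b]
        gap = max(ib.min() - ia.max(), ia.min() - ib.max())
        rows.append(
            {
                "label_a": a,
                "label_b": b,
                "disjoint": bool(gap > 0),
                "gap": float(gap),
                "range_a_min": float(ia.min()),
                "range_a_max": float(ia.max()),
                "range_b_min": float(ib.min()),
                "range_b_max": float(ib.max()),
            }
        )
    return pd.DataFrame(rows, columns=[
        "label_a", "label_b", "disjoint", "gap",
        "range_a_min", "range_a_max", "range_b_min", "range_b_max",
    ])
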