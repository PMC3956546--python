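"""Sample clustering: correlation distance, classical MDS, silhouette.

Samples (columns of a profile matrix) are compared by one minus
Pearson's correlation coefficient, embedded by classical (Torgerson)
multidimensional scaling — double-center -D^2/2, eigendecompose, scale
eigenvectors by the square root of the non-negative eigenvalues — and
cluster separation by a labelling is summarized as the mean silhouette
width in the embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score


@dataclass
class DistanceMatrix:
    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T) or not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")


@dataclass
class EmbeddingCoords:
    ids: tuple[str, ...]
    coords: np.ndarray       # n x k, centered columns
    eigenvalues: np.ndarray  # k, non-increasing

    def to_frame(self) -> pd.DataFrame:
        cols = [f"dim{i+1}" for i in range(self.coords.shape[1])]
        return pd.DataFrame(self.coords, index=list(self.ids), columns=cols)


def pearson_distance(profiles: pd.DataFrame) -> DistanceMatrix:
    """1 - Pearson r between sample columns of a features-by-samples matrix."""
    if profiles.shape[1] < 2 or profiles.shape[0] < 2:
        raise ValueError("need >= 2 samples and >= 2 features")
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=0)
    dead = profiles.columns[sd == 0.0]
    if len(dead):
        raise ValueError(f"zero-variance sample(s): {list(dead)}")
    r = np.corrcoef(X, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0  # enforce exact symmetry against float noise
    return DistanceMatrix(tuple(map(str, profiles.columns)), d)


def classical_mds(D: DistanceMatrix, k: int = 2) -> EmbeddingCoords:
    """Torgerson MDS of a distance matrix into k dimensions.

    Negative eigenvalues (non-Euclidean distances) are truncated.  Axes
    are ordered by non-increasing eigenvalue and signed so the
    largest-magnitude coordinate on each axis is positive, making the
    embedding deterministic.
    """
    n = len(D.ids)
    if not (1 <= k <= n - 1):
        raise ValueError(f"k must be in [1, {n - 1}]")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D.d ** 2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if vals[0] <= 0:
        raise ValueError("no positive eigenvalue; distances carry no configuration")
    vals_k = vals[:k].clip(min=0.0)
    coords = vecs[:, :k] * np.sqrt(vals_k)
    for a in range(k):
        col = coords[:, a]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, a] = -col
    return EmbeddingCoords(D.ids, coords, vals_k)


def cluster_separation(coords: EmbeddingCoords, labels: Sequence[str]) -> float:
    """Mean silhouette width of a labelling in the embedding (Euclidean)."""
    labels = list(labels)
    if len(labels) != len(coords.ids):
        raise ValueError("one label per sample required")
    if len(set(labels)) < 2:
        raise ValueError("silhouette needs at least 2 distinct labels")
    return float(silhouette_score(coords.coords, labels, metric="euclidean"))


def drug_score_matrix(reports) -> pd.DataFrame:
    """Drugs-by-samples matrix of summary scores; absent calls encoded as 0."""
    cols = {}
    for rep in reports:
        cols[rep.sample_id] = {s.drug: s.summary_score for s in rep.ranked}
    return pd.DataFrame(cols).fillna(0.0).sort_index()
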