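"""Posterior point estimate of the innovation-rate clustering.

From retained Gibbs draws the posterior co-clustering probabilities yield
a dissimilarity d_rt = Pr{lambda_r != lambda_t | y} between epochs.  D is
symmetric with zero diagonal and entries in [0, 1] but is generally not a
metric, so the epochs are first embedded in the plane by classical
(Torgerson) multidimensional scaling and the embedding is then cut by
Ward-linkage hierarchical clustering into a fixed number of groups.  When
the generating component of each innovation is known (simulated data), the
labelling is scored by a permutation-matched confusion matrix.

Equality of two rates within a draw is tested with exact floating-point
comparison: members of a cluster share one atom by construction (the
refresh step assigns the identical value to all of them), so exact
equality is the correct test, not a tolerance.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .gibbs import PosteriorDraws

__all__ = [
    "DissimilarityMatrix",
    "ClusterSolution",
    "coclustering_dissimilarity",
    "mds_embed_2d",
    "cut_clusters",
    "confusion_and_accuracy",
    "cluster_point_estimate",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Co-clustering dissimilarities d_rt = Pr{lambda_r != lambda_t | y}."""

    d: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.d, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("dissimilarity matrix must be square")
        if not np.allclose(d, d.T):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if d.min() < -1e-12 or d.max() > 1 + 1e-12:
            raise ValueError("dissimilarity entries must lie in [0, 1]")
        object.__setattr__(self, "d", np.clip(d, 0.0, 1.0))

    @property
    def n(self) -> int:
        return self.d.shape[0]


@dataclass(frozen=True)
class ClusterSolution:
    """Per-epoch labels with the 2-D embedding behind them.

    ``confusion[i, j]`` counts epochs with predicted label i + 1 and true
    component j + 1 after the accuracy-maximizing permutation matching.
    """

    embedding: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) in 1..n_clusters
    n_clusters: int
    confusion: np.ndarray | None = None
    accuracy: float | None = None

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "epoch_offset": np.arange(1, len(self.labels) + 1),
                "mds1": self.embedding[:, 0],
                "mds2": self.embedding[:, 1],
                "label": self.labels,
            }
        ).to_csv(path, index=False)


def coclustering_dissimilarity(draws: PosteriorDraws) -> DissimilarityMatrix:
    """Monte-Carlo estimate of d_rt from retained draws.

    Uses the co-clustering tallies accumulated during the run when
    available, otherwise recomputes them from stored rate draws by exact
    equality of atoms.
    """
    if draws.n_retained < 1:
        raise ValueError("need at least one retained draw")
    if draws.cocluster_counts is not None:
        same = draws.cocluster_counts / draws.n_retained
    elif draws.rates is not None:
        n = draws.n_epochs
        same = np.zeros((n, n))
        for row in draws.rates:
            same += row[:, None] == row[None, :]
        same /= draws.n_retained
    else:
        raise ValueError("draws carry neither co-clustering tallies nor rate draws")
    d = 1.0 - same
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(d=d)


def mds_embed_2d(d: DissimilarityMatrix) -> tuple[np.ndarray, float]:
    """Classical (Torgerson) metric MDS into the plane.

    Double-centers -d^2/2, takes the two leading eigenpairs and clips
    negative eigenvalues to zero (D need not be Euclidean).  Deterministic
    given its input.  Returns the (n, 2) coordinates and the stress,
    ``sqrt(sum (d_ij - dhat_ij)^2 / sum d_ij^2)`` (0 for an all-zero D).
    """
    dm = d.d
    n = d.n
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dm**2) @ j
    eigval, eigvec = np.linalg.eigh(b)
    top = np.argsort(eigval)[::-1][:2]
    lam = np.clip(eigval[top], 0.0, None)
    coords = eigvec[:, top] * np.sqrt(lam)
    denom = float(np.sum(dm**2))
    if denom == 0.0:
        return coords, 0.0
    dhat = np.zeros_like(dm)
    idx = np.triu_indices(n, 1)
    dhat[idx] = pdist(coords)
    dhat += dhat.T
    stress = float(np.sqrt(np.sum((dm - dhat) ** 2) / denom))
    return coords, stress


def cut_clusters(embedding: np.ndarray, n_clusters: int, method: str = "ward") -> np.ndarray:
    """Hierarchical clustering of the embedding, cut to n_clusters labels.

    Ward linkage on Euclidean distances by default; labels are 1-based.
    """
    embedding = np.asarray(embedding, dtype=float)
    n = embedding.shape[0]
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in 1..{n}")
    if n_clusters == n:
        return np.arange(1, n + 1)
    z = linkage(embedding, method=method)
    return fcluster(z, t=n_clusters, criterion="maxclust")


def confusion_and_accuracy(
    predicted: np.ndarray, truth: np.ndarray
) -> tuple[np.ndarray, float]:
    """Permutation-matched confusion matrix and accuracy.

    Predicted labels are relabelled by the permutation maximizing the
    confusion-matrix trace (exhaustive search, supported up to 6 predicted
    label values); accuracy is trace/total after matching.  Rows index
    predicted clusters, columns true components.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and true label vectors must have equal length")
    pred_vals = np.unique(predicted)
    true_vals = np.unique(truth)
    if len(pred_vals) > 6:
        raise ValueError("permutation matching supports at most 6 predicted clusters")
    k = max(len(pred_vals), len(true_vals))
    pred_idx = np.searchsorted(pred_vals, predicted)
    true_idx = np.searchsorted(true_vals, truth)
    raw = np.zeros((k, k), dtype=np.int64)
    np.add.at(raw, (pred_idx, true_idx), 1)
    best_perm = None
    best_trace = -1
    for perm in itertools.permutations(range(k)):
        tr = int(sum(raw[perm[j], j] for j in range(k)))
        if tr > best_trace:
            best_trace = tr
            best_perm = perm
    conf = raw[list(best_perm), :]
    accuracy = best_trace / len(predicted)
    return conf, float(accuracy)


def cluster_point_estimate(
    draws: PosteriorDraws,
    n_clusters: int | None = None,
    truth: np.ndarray | None = None,
) -> ClusterSolution:
    """Full dissimilarity -> MDS -> Ward pipeline from posterior draws.

    ``n_clusters`` defaults to the posterior mode of K.  When the true
    generating components are supplied the solution carries the
    permutation-matched confusion matrix and accuracy.
    """
    if n_clusters is None:
        n_clusters = draws.k_mode()
    d = coclustering_dissimilarity(draws)
    embedding, _ = mds_embed_2d(d)
    labels = cut_clusters(embedding, n_clusters)
    confusion = accuracy = None
    if truth is not None:
        confusion, accuracy = confusion_and_accuracy(labels, truth)
    return ClusterSolution(
        embedding=embedding,
        labels=np.asarray(labels),
        n_clusters=int(n_clusters),
        confusion=confusion,
        accuracy=accuracy,
    )
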