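"""Sample-level structure: clustering, PCA, classical MDS, first-year change.

These summaries answer the coarse questions asked of a developmental
expression panel before any tipping-point analysis: do samples cluster by
species, how much of the expression variation is a one-dimensional age
trajectory, and what fraction of that trajectory is traversed in the first
year of life.

Classical (Torgerson) MDS on Euclidean distances is used for the 1-D
trajectory; it is deterministic and equals the PCA first axis up to sign,
which the test suite asserts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .dataset import ExpressionDataset

logger = logging.getLogger("dnbdev")

__all__ = [
    "OrdinationResult",
    "cluster_samples",
    "pca_scores",
    "mds_axis",
    "fraction_change_by_age",
]


@dataclass(frozen=True)
class OrdinationResult:
    """Low-dimensional sample coordinates from PCA or classical MDS."""

    sample_ids: tuple
    coordinates: np.ndarray  # S x k
    variance_explained: tuple  # k floats, non-increasing (PCA; empty for cmds)
    method: str  # "pca" | "cmds"


def cluster_samples(
    ds: ExpressionDataset,
    method: str = "average",
    metric: str = "euclidean",
    k: int | None = None,
):
    """Agglomerative clustering of samples.

    Returns ``(merge_matrix, labels)``; ``labels`` is None unless ``k`` is
    given.  ``metric='correlation'`` uses 1 - Pearson r between sample
    profiles.
    """
    if method not in ("average", "complete", "ward"):
        raise ValueError(f"unsupported linkage {method!r}")
    if metric not in ("euclidean", "correlation"):
        raise ValueError(f"unsupported metric {metric!r}")
    s = ds.n_samples
    if s < 2:
        raise ValueError("need at least 2 samples to cluster")
    x = ds.values.to_numpy(dtype=float).T  # samples x genes
    dist = pdist(x, metric=metric)
    z = linkage(dist, method=method)
    labels = None
    if k is not None:
        if not (1 <= k <= s):
            raise ValueError(f"k={k} outside [1, {s}]")
        labels = fcluster(z, t=k, criterion="maxclust")
    return z, labels


def pca_scores(ds: ExpressionDataset, k: int = 2) -> OrdinationResult:
    """Top-k principal-component scores of the samples.

    Genes are centred (per gene, across samples) before decomposition.
    Each axis is oriented so that its largest-magnitude gene loading is
    positive, making scores reproducible across runs and libraries.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    g, s = ds.n_genes, ds.n_samples
    if k > min(g, s):
        raise ValueError(f"k={k} exceeds min(G, S)={min(g, s)}")
    x = ds.values.to_numpy(dtype=float)
    xc = x - x.mean(axis=1, keepdims=True)
    # columns of u are gene loadings; rows of (sv * vt.T) are sample scores
    u, sv, vt = np.linalg.svd(xc, full_matrices=False)
    scores = vt.T[:, :k] * sv[:k]
    loadings = u[:, :k]
    for j in range(k):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    total = float((sv**2).sum())
    var = tuple((sv[:k] ** 2 / total).tolist()) if total > 0 else tuple([0.0] * k)
    return OrdinationResult(
        sample_ids=tuple(ds.sample_ids),
        coordinates=scores,
        variance_explained=var,
        method="pca",
    )


def mds_axis(ds: ExpressionDataset) -> OrdinationResult:
    """First classical-MDS axis of Euclidean inter-sample distances.

    The axis is oriented so the youngest sample has a smaller coordinate
    than the oldest.  Degenerate input (all samples identical) yields an
    all-zero axis with a warning.
    """
    s = ds.n_samples
    if s < 3:
        raise ValueError("classical MDS needs at least 3 samples")
    x = ds.values.to_numpy(dtype=float).T
    sq = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
    j = np.eye(s) - np.ones((s, s)) / s
    b = -0.5 * j @ sq @ j
    vals, vecs = np.linalg.eigh(b)
    top = vals[-1]
    if top <= 1e-10:
        warnings.warn("all samples identical; MDS axis degenerate (zeros)")
        axis = np.zeros(s)
    else:
        axis = vecs[:, -1] * np.sqrt(top)
        ages = ds.ages
        youngest = int(np.argmin(ages))
        oldest = int(np.argmax(ages))
        if axis[youngest] > axis[oldest]:
            axis = -axis
    return OrdinationResult(
        sample_ids=tuple(ds.sample_ids),
        coordinates=axis[:, None],
        variance_explained=(),
        method="cmds",
    )


def fraction_change_by_age(
    axis: OrdinationResult, ages, cutoff_age: float
) -> float:
    """Fraction of the 1-D trajectory's range traversed by ``cutoff_age``.

    Defined as (range of coordinates among samples with age <= cutoff) /
    (range over all samples).  With a trajectory that is linear in age this
    is simply the fraction of the age span below the cutoff.
    """
    coords = np.asarray(axis.coordinates).ravel()
    ages = np.asarray(ages, dtype=float)
    if coords.size != ages.size:
        raise ValueError("ages must align with axis coordinates")
    early = coords[ages <= cutoff_age]
    if early.size == 0:
        raise ValueError("no samples at or below cutoff_age")
    if early.size == coords.size:
        warnings.warn("no samples beyond cutoff_age; fraction is 1 by definition")
        return 1.0
    total = coords.max() - coords.min()
    if total == 0:
        warnings.warn("degenerate axis (zero range); returning 0")
        return 0.0
    return float((early.max() - early.min()) / total)
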