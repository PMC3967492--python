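"""Feature space, smooth-cluster isolation and the Mahalanobis distance field.

Each vertex is mapped to the sorted eigenvalue triple of its normal voting
tensor.  k-means (k = 3 by default) partitions these feature points; the
cluster whose centroid has the largest first coordinate corresponds to the
smooth surface.  The feature distance of any vertex is then the squared
Mahalanobis distance of its feature point from that cluster's statistics:

    D(x) = (x - mu)^T Sigma^{-1} (x - mu).

D drives both the graph-cut segmentation penalties and the sharpening
weights; it is evaluated at every vertex, smooth-cluster members included.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

__all__ = [
    "SmoothSetStats",
    "DistanceField",
    "build_feature_points",
    "cluster_and_select_smooth",
    "mahalanobis_distance_field",
]

#: relative ridge added to the smooth covariance before inversion
COV_REGULARIZATION = 1e-6


@dataclass
class SmoothSetStats:
    """Membership and Gaussian statistics of the smooth cluster."""

    members: np.ndarray  # vertex ids
    mean: np.ndarray  # (3,)
    cov: np.ndarray  # (3, 3) raw covariance
    cov_inv: np.ndarray  # (3, 3) inverse of the regularised covariance


@dataclass
class DistanceField:
    """Per-vertex feature distance D >= 0 and its maximum."""

    values: np.ndarray
    d_max: float


def build_feature_points(eigenvalues: np.ndarray) -> np.ndarray:
    """Feature points: per-vertex sorted eigenvalue triples, shape (n, 3)."""
    pts = np.asarray(eigenvalues, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("eigenvalues must be an (n, 3) array")
    if (np.diff(pts, axis=1) > 1e-9).any() or (pts < -1e-9).any():
        raise ValueError("feature points must be non-negative and sorted descending")
    return np.clip(pts, 0.0, None)


def cluster_and_select_smooth(
    points: np.ndarray,
    k: int = 3,
    seed: int = 0,
    n_init: int = 10,
) -> SmoothSetStats:
    """k-means in feature space; the smooth set is the cluster whose centroid
    has the largest first coordinate (dominant single eigenvalue = flat)."""
    points = np.asarray(points, dtype=np.float64)
    n_distinct = len(np.unique(points, axis=0))
    if n_distinct < k:
        raise ValueError(
            f"only {n_distinct} distinct feature points; reduce k below {k}"
        )
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    labels = km.fit_predict(points)
    # smooth = the cluster most dominated by its largest eigenvalue.  The
    # fraction s1/(s1+s2+s3) measures how much tensor energy lies along the
    # principal direction; the raw first coordinate scales with sampling
    # density and can crown a densely-sampled feature band instead.  Tiny
    # clusters are ineligible: a handful of anomalous-valence vertices (fan
    # apices of revolution meshes) would otherwise hijack the selection and
    # degenerate the covariance.
    centers = km.cluster_centers_
    totals = np.maximum(centers.sum(axis=1), 1e-300)
    fractions = centers[:, 0] / totals
    sizes = np.bincount(labels, minlength=k)
    eligible = sizes >= max(1, int(0.05 * len(points)))
    if not eligible.any():
        eligible[:] = True
    fractions = np.where(eligible, fractions, -np.inf)
    smooth_label = int(np.argmax(fractions))
    members = np.nonzero(labels == smooth_label)[0]
    cluster = points[members]
    mu = cluster.mean(axis=0)
    cov = np.cov(cluster.T, bias=True) if len(cluster) > 1 else np.zeros((3, 3))
    cov = np.atleast_2d(cov)
    # relative ridge, floored by the squared feature-point scale so that a
    # cluster of (numerically) identical points still inverts sanely: members
    # then get D ~ 0 and anything separated gets a very large finite D
    scale = float((cluster**2).sum(axis=1).mean()) / 3.0
    ridge = COV_REGULARIZATION * max(
        np.trace(cov) / 3.0, COV_REGULARIZATION * scale
    )
    reg = cov + max(ridge, 1e-300) * np.eye(3)
    try:
        cov_inv = np.linalg.inv(reg)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate smooth set: covariance not invertible") from exc
    if not np.isfinite(cov_inv).all():
        raise ValueError("degenerate smooth set: covariance not invertible")
    return SmoothSetStats(members=members, mean=mu, cov=cov, cov_inv=cov_inv)


def mahalanobis_distance_field(
    points: np.ndarray, stats: SmoothSetStats
) -> DistanceField:
    """Mahalanobis distance of every feature point from the smooth set.

    The canonical distance, sqrt((x - mu)^T Sigma^{-1} (x - mu)).  Using the
    un-rooted quadratic form instead blows the field up quadratically with
    the cluster separation, saturating the exp(-alpha D) sharpening weights
    so the sharpness control loses all effect in its working range.
    """
    diff = np.asarray(points, dtype=np.float64) - stats.mean
    d = np.einsum("ni,ij,nj->n", diff, stats.cov_inv, diff)
    d = np.sqrt(np.clip(d, 0.0, None))
    return DistanceField(values=d, d_max=float(d.max()))
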