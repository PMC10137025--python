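"""Dynamic functional connectome patterns: twice-clustering and features.

Training WQCPs are clustered in two stages -- K-means overclustering into
``k0`` fine clusters, then Ward (or average/complete) agglomeration of the
K-means centroids -- and the pattern count K is chosen by the elbow
criterion on the total within-cluster sum of squares of the WQCPs. The K
centroids (member means) are the dynamic functional connectome patterns
(DFCPs), treated as recurring whole-brain connectivity states.

Two feature families are derived per subject:

* **ratio features** -- the fraction of the subject's WQCPs assigned (by
  nearest centroid) to each pattern, i.e. the state-occupancy distribution;
* **mean-beta features** -- the subject-average of the least-squares
  coefficients expressing each WQCP as a linear combination of the K
  centroids.

One code path serves training and test subjects: features always use
nearest-centroid assignment, never the clustering's internal labels.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.cluster import KMeans

from .data_model import DfcpModel, DfcpWarning, FeatureVector, ValidationError, Wqcp

__all__ = [
    "ClusteringParams",
    "twice_cluster",
    "elbow_select",
    "ratio_features",
    "beta_regress",
    "mean_beta",
    "assign_pattern",
    "dfcp_features",
]

_LINKAGES = ("ward", "average", "complete")


@dataclass(frozen=True)
class ClusteringParams:
    """Twice-clustering knobs.

    ``kmeans_k0`` is the overclustering size (``None``: 2*ceil(sqrt(n)),
    capped at n); ``k_candidates`` the candidate pattern counts scanned by
    the elbow rule; ``n_init`` the number of K-means restarts (best inertia
    kept); ``random_seed`` is required and recorded in the model.
    """

    kmeans_k0: int | None = None
    k_candidates: tuple[int, ...] = tuple(range(1, 11))
    linkage: str = "ward"
    n_init: int = 10
    random_seed: int = 0

    def __post_init__(self):
        if self.linkage not in _LINKAGES:
            raise ValidationError(f"linkage must be one of {_LINKAGES}")
        if self.n_init < 1:
            raise ValidationError("n_init must be >= 1")
        ks = tuple(sorted(int(k) for k in self.k_candidates))
        if not ks or ks[0] < 1:
            raise ValidationError("k_candidates must be positive integers")
        object.__setattr__(self, "k_candidates", ks)


def _wqcp_array(wqcps: Sequence[Wqcp]) -> np.ndarray:
    return np.vstack([w.values for w in wqcps])


def elbow_select(curve: np.ndarray, candidates: Sequence[int] | None = None) -> int:
    """Knee rule: the candidate maximizing perpendicular distance from the
    chord joining the curve's endpoints; ties take the smaller K.

    With fewer than 3 points there is no interior knee and the argmin of
    the curve is returned.
    """
    curve = np.asarray(curve, dtype=float)
    if candidates is None:
        candidates = np.arange(1, len(curve) + 1)
    candidates = np.asarray(list(candidates))
    if len(curve) != len(candidates):
        raise ValidationError("curve and candidate lengths differ")
    if len(curve) < 3:
        return int(candidates[int(np.argmin(curve))])
    x0, y0 = float(candidates[0]), curve[0]
    x1, y1 = float(candidates[-1]), curve[-1]
    dx, dy = x1 - x0, y1 - y0
    norm = math.hypot(dx, dy)
    if norm == 0:
        return int(candidates[0])
    # perpendicular distance of each point from the endpoint chord
    dist = np.abs(dy * (candidates - x0) - dx * (curve - y0)) / norm
    return int(candidates[int(np.argmax(dist))])  # argmax takes first (smaller K) on ties


def twice_cluster(wqcps: Sequence[Wqcp], p: ClusteringParams) -> DfcpModel:
    """Fit DFCPs by K-means overclustering plus hierarchical merging.

    Stage 1 runs K-means with ``k0`` centers (seeded, ``n_init`` restarts).
    Stage 2 builds a dendrogram over the stage-1 centroids and cuts it at
    every candidate K; each cut relabels the WQCPs through their K-means
    cluster, and the total within-cluster sum of squares of the WQCPs forms
    the elbow curve. Final centroids are member means at the elbow K.
    """
    if not wqcps:
        raise ValidationError("cannot cluster zero WQCPs")
    X = _wqcp_array(wqcps)
    n = X.shape[0]

    k0 = p.kmeans_k0 if p.kmeans_k0 is not None else min(2 * math.ceil(math.sqrt(n)), n)
    if k0 > n:
        warnings.warn(
            f"kmeans_k0={k0} exceeds the {n} available WQCPs; lowering to {n}",
            DfcpWarning,
            stacklevel=2,
        )
        k0 = n
    candidates = tuple(k for k in p.k_candidates if k <= k0)
    if not candidates:
        candidates = (k0,)

    km = KMeans(n_clusters=k0, n_init=p.n_init, random_state=p.random_seed)
    fine_labels = km.fit_predict(X)
    fine_centroids = km.cluster_centers_

    if k0 > 1:
        tree = linkage(fine_centroids, method=p.linkage, metric="euclidean")
    curve = []
    labelings = {}
    for K in candidates:
        if k0 == 1 or K >= k0:
            merged = np.arange(k0)
        else:
            merged = fcluster(tree, t=K, criterion="maxclust") - 1
        labels = merged[fine_labels]
        labelings[K] = labels
        wss = 0.0
        for c in np.unique(labels):
            member = X[labels == c]
            wss += float(((member - member.mean(axis=0)) ** 2).sum())
        curve.append(wss)
    curve = np.asarray(curve)

    K = elbow_select(curve, candidates)
    labels = labelings[K]
    present = np.unique(labels)
    centroids = np.column_stack([X[labels == c].mean(axis=0) for c in present])
    if centroids.shape[1] < K:
        # ties in the dendrogram can yield fewer than K distinct clusters
        # (e.g. all-identical WQCPs); pad with the grand mean so the model
        # carries the elbow-selected K
        pad = np.tile(X.mean(axis=0)[:, None], (1, K - centroids.shape[1]))
        centroids = np.column_stack([centroids, pad])
    return DfcpModel(
        centroids=centroids,
        kmeans_k0=k0,
        linkage=p.linkage,
        k_candidates=candidates,
        elbow_curve=curve,
        random_seed=p.random_seed,
    )


def assign_pattern(wqcp: Wqcp | np.ndarray, model: DfcpModel) -> int:
    """Index of the nearest centroid (Euclidean); ties go to the lowest index."""
    v = wqcp.values if isinstance(wqcp, Wqcp) else np.asarray(wqcp, dtype=float)
    d = np.linalg.norm(model.centroids - v[:, None], axis=0)
    return int(np.argmin(d))


def beta_regress(wqcp: Wqcp | np.ndarray, model: DfcpModel) -> np.ndarray:
    """Least-squares coefficients of the WQCP on the K centroids (no intercept).

    Minimum-norm solution when centroids are rank-deficient.
    """
    v = wqcp.values if isinstance(wqcp, Wqcp) else np.asarray(wqcp, dtype=float)
    beta, *_ = np.linalg.lstsq(model.centroids, v, rcond=None)
    return beta


def ratio_features(assignments: Sequence[int], K: int) -> np.ndarray:
    """Occupancy distribution: fraction of the subject's WQCPs in each pattern."""
    assignments = np.asarray(list(assignments), dtype=int)
    if assignments.size == 0:
        warnings.warn("subject has zero WQCPs; ratio features zeroed", DfcpWarning, stacklevel=2)
        return np.zeros(K)
    return np.bincount(assignments, minlength=K) / assignments.size


def mean_beta(betas: Sequence[np.ndarray], K: int | None = None) -> np.ndarray:
    """Elementwise mean of a subject's beta vectors."""
    betas = list(betas)
    if not betas:
        if K is None:
            raise ValidationError("empty beta list needs an explicit K")
        warnings.warn("subject has zero WQCPs; mean betas zeroed", DfcpWarning, stacklevel=2)
        return np.zeros(K)
    return np.mean(np.vstack(betas), axis=0)


def dfcp_features(
    wqcps: Sequence[Wqcp],
    model: DfcpModel,
    subject_id: str,
    group: str,
    sfc_strength: np.ndarray | None = None,
) -> FeatureVector:
    """Per-subject feature vector: [ratios (K), mean betas (K), optional sFC (N)]."""
    K = model.K
    if wqcps:
        assignments = [assign_pattern(w, model) for w in wqcps]
        ratios = ratio_features(assignments, K)
        betas = mean_beta([beta_regress(w, model) for w in wqcps], K)
        flagged = False
    else:
        ratios = ratio_features([], K)
        betas = np.zeros(K)
        flagged = True
    return FeatureVector(
        ratios=ratios,
        mean_betas=betas,
        sfc_strength=sfc_strength,
        subject_id=subject_id,
        group=group,
        flagged=flagged,
    )
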