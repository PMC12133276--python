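"""Density-based clustering of the active-site score matrix.

DBSCAN runs directly on the precomputed distances.  A point is a core point
if at least ``min_samples`` points (itself included) lie within distance
``eps``; clusters are the connected components of core points under
eps-reachability together with their border points.  Border points reachable
from several clusters are claimed by the cluster formed first under
index-order expansion, which makes the labeling fully deterministic for a
fixed input order.  Points in no cluster are noise and reported with label 0;
clusters are numbered 1..K by decreasing size (ties broken by the smallest
contained member index).

Parameters can be supplied explicitly or chosen automatically:
``min_samples = max(5, round(ln n))``, and ``eps`` by quality selection over
the k-distance curve — every distinct value of the curve (each point's
distance to its min_samples-th nearest point) is a candidate neighborhood
radius, and the candidate whose clustering maximizes the noise-penalized
mean silhouette (silhouette of the clustered points times the clustered
fraction) is chosen, ties going to the larger radius.  The silhouette term
rejects radii that merge well-separated groups; the clustered-fraction term
rejects radii so tight that genuine group members are shed as noise.
"""

from __future__ import annotations

import logging
import math
from collections import deque
from dataclasses import dataclass

import numpy as np

from .scoring import ScoreMatrix

logger = logging.getLogger("asclust")

#: noise label in all user-facing outputs
NOISE = 0

_EPS_FLOOR = 1e-6


@dataclass(frozen=True)
class ClusteringParams:
    eps: float
    min_samples: int
    auto: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.eps <= 1.0:
            raise ValueError(f"eps {self.eps} outside (0, 1]")
        if self.min_samples < 1:
            raise ValueError(f"min_samples {self.min_samples} must be >= 1")


@dataclass(frozen=True)
class ClusteringResult:
    member_ids: tuple[str, ...]
    labels: tuple[int, ...]  # 1..K clusters, 0 noise
    params: ClusteringParams
    cluster_sizes: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_sizes)

    def members_of(self, label: int) -> list[str]:
        return [m for m, l in zip(self.member_ids, self.labels) if l == label]


def order_clusters(raw_labels: np.ndarray) -> np.ndarray:
    """Renumber raw labels (-1 = noise, arbitrary non-negative ints = clusters)
    to 1..K by decreasing size, ties by smallest contained member index."""
    raw_labels = np.asarray(raw_labels)
    out = np.zeros(len(raw_labels), dtype=int)
    stats = []
    for lab in np.unique(raw_labels):
        if lab < 0:
            continue
        idx = np.nonzero(raw_labels == lab)[0]
        stats.append((-len(idx), int(idx.min()), lab))
    stats.sort()
    for new, (_, _, old) in enumerate(stats, start=1):
        out[raw_labels == old] = new
    return out


def dbscan(score: ScoreMatrix, params: ClusteringParams) -> ClusteringResult:
    """DBSCAN on precomputed distances with deterministic index-order expansion."""
    n = len(score)
    if params.min_samples > n:
        raise ValueError(
            f"min_samples {params.min_samples} exceeds the number of members {n}"
        )
    D = score.values
    neighbors = [np.nonzero(D[i] <= params.eps)[0] for i in range(n)]
    core = np.array([len(nb) >= params.min_samples for nb in neighbors])

    raw = np.full(n, -1, dtype=int)
    cluster = -1
    for seed in range(n):
        if raw[seed] != -1 or not core[seed]:
            continue
        cluster += 1
        raw[seed] = cluster
        queue = deque([seed])
        while queue:
            q = queue.popleft()
            if not core[q]:
                continue
            for nb in neighbors[q]:
                if raw[nb] == -1:
                    raw[nb] = cluster
                    queue.append(nb)

    labels = order_clusters(raw)
    sizes = {int(l): int((labels == l).sum()) for l in np.unique(labels) if l != NOISE}
    return ClusteringResult(score.member_ids, tuple(int(l) for l in labels),
                            params, sizes)


#: cap on the number of candidate eps values scanned by auto_params
_MAX_CANDIDATES = 32


def _candidate_eps(k_dist: np.ndarray) -> np.ndarray:
    """Distinct positive k-distance values, thinned to a bounded grid."""
    cand = np.unique(k_dist)
    cand = cand[cand > 0.0]
    if len(cand) > _MAX_CANDIDATES:
        idx = np.unique(
            np.round(np.linspace(0, len(cand) - 1, _MAX_CANDIDATES)).astype(int)
        )
        cand = cand[idx]
    return cand


def auto_params(score: ScoreMatrix) -> ClusteringParams:
    """Choose eps and min_samples from the data.

    min_samples = max(5, round(ln n)).  eps comes from the k-distance curve
    (every point's distance to its min_samples-th nearest point, self
    included): each distinct curve value is tried as a neighborhood radius
    and the one whose DBSCAN run maximizes the noise-penalized mean
    silhouette — mean silhouette of the clustered points, computed on the
    precomputed distances, multiplied by the fraction of points clustered —
    is selected, ties resolved toward the larger radius.  Radii yielding
    fewer than two clusters score lowest and are chosen only when no radius
    separates anything, in which case the largest candidate is used (one
    cluster results).  A flat curve falls back to the constant value; a
    curve of all zeros falls back to a tiny positive radius.
    """
    n = len(score)
    if n < 5:
        raise ValueError(
            f"automatic parameter selection needs at least 5 members (got {n}); "
            "supply eps and min_samples manually"
        )
    min_samples = max(5, round(math.log(n)))
    k_dist = np.sort(np.sort(score.values, axis=1)[:, min_samples - 1])

    candidates = _candidate_eps(k_dist)
    if len(candidates) == 0:
        eps = _EPS_FLOOR  # every point has min_samples duplicates of itself
    elif len(candidates) == 1:
        eps = float(candidates[0])  # flat curve: the constant k-distance
    else:
        from sklearn.metrics import silhouette_score

        best_quality, eps = -math.inf, float(candidates[-1])
        for c in candidates:
            c = float(min(c, 1.0))
            trial = dbscan(score, ClusteringParams(eps=c,
                                                   min_samples=min_samples))
            labels = np.asarray(trial.labels)
            mask = labels != NOISE
            if trial.n_clusters < 2 or mask.sum() <= trial.n_clusters:
                continue
            sil = silhouette_score(
                score.values[np.ix_(mask, mask)], labels[mask],
                metric="precomputed")
            quality = float(sil) * float(mask.mean())
            if quality >= best_quality:
                best_quality, eps = quality, c
    eps = min(max(eps, _EPS_FLOOR), 1.0)
    logger.info("auto-selected DBSCAN parameters: eps=%.4f min_samples=%d", eps,
                min_samples)
    return ClusteringParams(eps=eps, min_samples=min_samples, auto=True)


def recluster(
    result: ClusteringResult,
    score: ScoreMatrix,
    cluster_label: int,
    params: ClusteringParams | None = None,
) -> ClusteringResult:
    """Re-run DBSCAN on the members of one cluster to expose substructure.

    ``params=None`` recomputes automatic parameters on the restricted score
    matrix.  A subset too small to cluster is returned as a single cluster
    with a warning.
    """
    if cluster_label not in result.cluster_sizes:
        raise ValueError(
            f"cluster label {cluster_label} not present "
            f"(available: {sorted(result.cluster_sizes)})"
        )
    members = result.members_of(cluster_label)
    sub = score.submatrix(members)

    if params is None:
        try:
            sub_params = auto_params(sub)
        except ValueError:
            logger.warning(
                "cluster %d has only %d members; returning it unsplit",
                cluster_label, len(members),
            )
            fallback = ClusteringParams(eps=1.0, min_samples=1, auto=True)
            return ClusteringResult(
                tuple(members), tuple([1] * len(members)), fallback,
                {1: len(members)},
            )
    else:
        sub_params = params
        if sub_params.min_samples > len(members):
            logger.warning(
                "cluster %d smaller than min_samples %d; returning it unsplit",
                cluster_label, sub_params.min_samples,
            )
            return ClusteringResult(
                tuple(members), tuple([1] * len(members)), sub_params,
                {1: len(members)},
            )
    return dbscan(sub, sub_params)
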