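"""Nearest-centroid sleep staging on the (weighted rate, relative voltage) plane.

Five cluster centroids — one per sleep stage — are learned by Lloyd's
k-means on scaled training features (or, alternatively, taken as the
per-stage means of labeled features).  A new point (a, b) is assigned to
the stage of the centroid (x_i, y_i) minimizing the Euclidean distance

    D_i = sqrt((x_i - a)^2 + (y_i - b)^2).

The k-means here is written out rather than delegated because the staging
method is exactly this clustering: the initialization (greedy farthest-point
from a seeded random first center), the empty-cluster reseeding rule and the
per-iteration objective are part of the method's contract and are asserted
by tests.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import (AmbiguousLabelError, EmptyClusterError, InvalidModelError,
                     InvalidParameterError)
from .processing import FeatureVector
from .scaling import ScalingConfig
from .stages import STAGE_ORDER, SleepStage


@dataclass(frozen=True)
class Centroid:
    """A labeled cluster center (x_i, y_i); index_i is 1-based."""

    index_i: int
    x: float
    y: float
    stage: SleepStage | None = None

    def __post_init__(self):
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise InvalidParameterError("centroid coordinates must be finite")
        if self.index_i < 1:
            raise InvalidParameterError("centroid index is 1-based")


@dataclass
class CentroidSet:
    """The k centroids plus the scaling under which they were fitted."""

    centroids: list[Centroid]
    scaling: ScalingConfig | None = None
    metadata: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.centroids)

    @property
    def labeled(self) -> bool:
        return all(c.stage is not None for c in self.centroids)


def _coords(point) -> tuple[float, float]:
    if isinstance(point, FeatureVector):
        a, b = point.rate_bpm, point.voltage
    else:
        a, b = point
    if not (math.isfinite(a) and math.isfinite(b)):
        raise InvalidParameterError("point coordinates must be finite")
    return float(a), float(b)


def euclidean_distance(point, centroid: Centroid) -> float:
    """D_i = sqrt((x_i - a)^2 + (y_i - b)^2) for a point (a, b)."""
    a, b = _coords(point)
    return math.hypot(centroid.x - a, centroid.y - b)


def _as_matrix(points: Sequence[FeatureVector]) -> np.ndarray:
    return np.array([_coords(p) for p in points], dtype=float)


def _farthest_point_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy spread: seeded random first center, then max-min distance."""
    centers = [X[int(rng.integers(len(X)))]]
    for _ in range(1, k):
        d2 = np.min([np.sum((X - c) ** 2, axis=1) for c in centers], axis=0)
        centers.append(X[int(np.argmax(d2))])
    return np.array(centers)


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int, tol: float
           ) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Lloyd iterations; returns (centers, assignment, objective, history)."""
    k = len(centers)
    history: list[float] = []
    assign = np.zeros(len(X), dtype=int)
    for _ in range(max_iter):
        d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
        assign = np.argmin(d2, axis=1)  # ties -> lowest cluster index
        history.append(float(d2[np.arange(len(X)), assign].sum()))
        new_centers = centers.copy()
        for j in range(k):
            members = X[assign == j]
            if members.size:
                new_centers[j] = members.mean(axis=0)
            else:
                # reseed an empty cluster at the point farthest from its
                # currently assigned centroid
                worst = int(np.argmax(d2[np.arange(len(X)), assign]))
                new_centers[j] = X[worst]
        shift = float(np.max(np.linalg.norm(new_centers - centers, axis=1)))
        centers = new_centers
        if shift < tol:
            break
    d2 = np.sum((X[:, None, :] - centers[None, :, :]) ** 2, axis=2)
    assign = np.argmin(d2, axis=1)
    objective = float(d2[np.arange(len(X)), assign].sum())
    history.append(objective)
    return centers, assign, objective, history


def fit_centroids(points: Sequence[FeatureVector], k: int = 5, seed: int = 0,
                  n_init: int = 10, max_iter: int = 300, tol: float = 1e-6,
                  scaling: ScalingConfig | None = None) -> CentroidSet:
    """Unsupervised k-means fit: best of ``n_init`` seeded restarts by WCSS.

    Deterministic for a fixed seed; restarts share one generator so the whole
    fit replays bit-identically.  The winning run's per-iteration objective
    history is stored in ``metadata["history"]`` (non-increasing by
    construction of Lloyd's algorithm).
    """
    if len(points) < k:
        raise InvalidParameterError(f"need at least k={k} points, got {len(points)}")
    if k < 1:
        raise InvalidParameterError("k must be >= 1")
    X = _as_matrix(points)
    rng = np.random.default_rng(seed)
    best = None
    for init_idx in range(n_init):
        centers0 = _farthest_point_init(X, k, rng)
        centers, assign, objective, history = _lloyd(X, centers0, max_iter, tol)
        if best is None or objective < best[2] - 1e-15:
            best = (centers, assign, objective, history)
    centers, assign, objective, history = best
    centroids = [Centroid(index_i=j + 1, x=float(c[0]), y=float(c[1]))
                 for j, c in enumerate(centers)]
    return CentroidSet(centroids, scaling=scaling,
                       metadata={"seed": seed, "n_init": n_init,
                                 "objective": objective, "history": history})


def stage_mean_centroids(points: Sequence[FeatureVector],
                         scaling: ScalingConfig | None = None) -> CentroidSet:
    """Supervised alternative: one centroid per stage at the stage's mean.

    Useful when stage-featured training data are available; centroids are
    ordered by the canonical stage order.
    """
    by_stage: dict[SleepStage, list[tuple[float, float]]] = {}
    for p in points:
        if p.stage_label is None:
            raise InvalidParameterError("stage_mean_centroids needs labeled points")
        by_stage.setdefault(p.stage_label, []).append(_coords(p))
    centroids = []
    for j, stage in enumerate(s for s in STAGE_ORDER if s in by_stage):
        arr = np.array(by_stage[stage])
        centroids.append(Centroid(index_i=j + 1, x=float(arr[:, 0].mean()),
                                  y=float(arr[:, 1].mean()), stage=stage))
    return CentroidSet(centroids, scaling=scaling,
                       metadata={"mode": "supervised", "n": len(points)})


def assign_clusters(points: Sequence[FeatureVector], cset: CentroidSet) -> np.ndarray:
    """Index of the nearest centroid for each point (ties -> lowest index)."""
    X = _as_matrix(points)
    C = np.array([[c.x, c.y] for c in cset.centroids])
    d2 = np.sum((X[:, None, :] - C[None, :, :]) ** 2, axis=2)
    return np.argmin(d2, axis=1)


def label_centroids(cset: CentroidSet, labeled_points: Sequence[FeatureVector],
                    strict: bool = True) -> CentroidSet:
    """Attach a stage to each centroid from the labeled points it attracts.

    Every cluster must receive at least one labeled point.  In strict mode
    (default) a within-cluster majority tie, or two clusters whose majority
    is the same stage, raises :class:`AmbiguousLabelError`.  In lenient mode
    the (cluster, stage) pairs are matched greedily by descending count,
    ties broken by lowest cluster index then stage order, which yields
    distinct labels whenever enough stages are present.
    """
    if any(p.stage_label is None for p in labeled_points):
        raise InvalidParameterError("label_centroids needs labeled points")
    assign = assign_clusters(labeled_points, cset)
    counts: list[Counter] = [Counter() for _ in range(cset.k)]
    for p, j in zip(labeled_points, assign):
        counts[j][p.stage_label] += 1
    for j, c in enumerate(counts):
        if not c:
            raise EmptyClusterError(f"cluster {j + 1} received no labeled points")

    if strict:
        labels: list[SleepStage] = []
        for j, c in enumerate(counts):
            top = c.most_common()
            if len(top) > 1 and top[0][1] == top[1][1]:
                raise AmbiguousLabelError(
                    f"cluster {j + 1}: majority tie between "
                    f"{top[0][0].name} and {top[1][0].name}")
            labels.append(top[0][0])
        if len(set(labels)) != len(labels):
            dup = [s.name for s, n in Counter(labels).items() if n > 1]
            raise AmbiguousLabelError(f"stage(s) {dup} claimed by multiple clusters")
    else:
        pairs = sorted(
            ((n, j, stage) for j, c in enumerate(counts) for stage, n in c.items()),
            key=lambda t: (-t[0], t[1], t[2]))
        labels_by_cluster: dict[int, SleepStage] = {}
        used: set[SleepStage] = set()
        for n, j, stage in pairs:
            if j in labels_by_cluster or stage in used:
                continue
            labels_by_cluster[j] = stage
            used.add(stage)
        # clusters left over (more clusters than stages): take raw majority
        for j, c in enumerate(counts):
            labels_by_cluster.setdefault(j, c.most_common(1)[0][0])
        labels = [labels_by_cluster[j] for j in range(cset.k)]

    centroids = [replace(c, stage=s) for c, s in zip(cset.centroids, labels)]
    return CentroidSet(centroids, scaling=cset.scaling, metadata=dict(cset.metadata))


def classify(point, cset: CentroidSet) -> SleepStage:
    """Stage of the centroid with the smallest distance D_i to the point.

    An exact distance tie is broken by the lowest cluster index.
    """
    if not cset.labeled:
        raise InvalidModelError("centroid set is not fully labeled")
    best_stage, best_d = None, math.inf
    for c in cset.centroids:
        d = euclidean_distance(point, c)
        if d < best_d:
            best_stage, best_d = c.stage, d
    return best_stage


def classify_session(features: Sequence[FeatureVector],
                     cset: CentroidSet) -> list[SleepStage]:
    """Classify each window feature in order, giving a predicted hypnogram."""
    out = []
    for idx, f in enumerate(features):
        try:
            out.append(classify(f, cset))
        except InvalidParameterError as exc:
            raise InvalidParameterError(f"window {idx}: {exc}") from exc
    return out
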