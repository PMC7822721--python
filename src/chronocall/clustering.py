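"""Cohort-level chronotype clustering.

Each person is embedded as a point in the plane spanned by their two
activity-period peak hours, in dominance order: x is the primary
(highest-weight) peak, y the secondary.  The cohort is then partitioned
with k-means (Lloyd's algorithm with k-means++ seeding, implemented
here rather than delegated, so that seeding, tie-breaking and
empty-cluster repair are fully specified).  With k = 2 the cluster
whose centroid has the earlier primary-peak coordinate is labeled
*morningness*, the other *eveningness*.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .chronotype import ModeRanking

logger = logging.getLogger(__name__)

PERIOD = 24.0

MORNINGNESS = "morningness"
EVENINGNESS = "eveningness"


class ClusteringError(ValueError):
    """Raised on invalid clustering input."""


@dataclass(frozen=True)
class EmbeddedPoint:
    """A person's position in chronotype space: (primary peak hour,
    secondary peak hour), both in [0, 24)."""

    person_id: str
    x: float
    y: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x < PERIOD and 0.0 <= self.y < PERIOD):
            raise ClusteringError("coordinates must lie in [0, 24)")


@dataclass
class ClusterResult:
    """k-means output: centroids (in the embedding's hour coordinates),
    per-person assignments, within-cluster sum of squares, and — for
    bipartite clustering — morningness/eveningness labels."""

    k: int
    centroids: np.ndarray
    assignments: dict[str, int]
    inertia: float
    labels: dict[int, str] = field(default_factory=dict)

    def label_of(self, person_id: str) -> str:
        return self.labels[self.assignments[person_id]]


def embed(rankings: list[ModeRanking]) -> list[EmbeddedPoint]:
    """Map ranked modes to 2D points (primary peak, secondary peak).

    Dominance order is kept: a morning-dominant and an evening-dominant
    person sharing the same two peak hours map to distinct, mirrored
    points.  Rankings with a single period cannot be embedded and are
    excluded with a warning.
    """
    points = []
    for r in rankings:
        if len(r.periods) < 2:
            warnings.warn(
                f"{r.person_id}: single activity period, excluded from embedding",
                stacklevel=2,
            )
            continue
        points.append(
            EmbeddedPoint(r.person_id, x=r.primary.peak_hour, y=r.secondary.peak_hour)
        )
    return points


def _torus_coords(xy: np.ndarray) -> np.ndarray:
    """Embed hour coordinates on the torus via sin/cos pairs scaled so
    that small distances match plain hour differences."""
    r = PERIOD / (2.0 * np.pi)
    theta = xy * (2.0 * np.pi / PERIOD)
    return np.column_stack(
        [r * np.cos(theta[:, 0]), r * np.sin(theta[:, 0]),
         r * np.cos(theta[:, 1]), r * np.sin(theta[:, 1])]
    )


def _kmeanspp(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    centers = [X[rng.integers(len(X))]]
    while len(centers) < k:
        d2 = ((X[:, None, :] - np.array(centers)[None, :, :]) ** 2).sum(-1).min(1)
        total = d2.sum()
        if total <= 0:
            centers.append(X[rng.integers(len(X))])
        else:
            centers.append(X[rng.choice(len(X), p=d2 / total)])
    return np.array(centers)


def _lloyd(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int
) -> tuple[np.ndarray, np.ndarray, float]:
    centers = _kmeanspp(X, k, rng)
    assign = np.full(len(X), -1)
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
        new_assign = d2.argmin(1)
        # empty-cluster repair: reseed to the point farthest from its center
        for c in range(k):
            if not (new_assign == c).any():
                far = d2[np.arange(len(X)), new_assign].argmax()
                centers[c] = X[far]
                d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(-1)
                new_assign = d2.argmin(1)
        if (new_assign == assign).all():
            break
        assign = new_assign
        for c in range(k):
            centers[c] = X[assign == c].mean(axis=0)
    d2 = ((X - centers[assign]) ** 2).sum()
    return centers, assign, float(d2)


def kmeans(
    points: list[EmbeddedPoint],
    k: int = 2,
    n_init: int = 20,
    max_iter: int = 300,
    seed: int | np.random.Generator = 0,
    metric: str = "euclidean",
) -> ClusterResult:
    """Partition embedded persons with k-means.

    Lloyd's iterations from k-means++ seeds, best of ``n_init``
    restarts by inertia; deterministic given ``seed``.  ``metric`` is
    ``"euclidean"`` (plain hour coordinates, the default) or
    ``"circular"`` (coordinates mapped to sin/cos pairs on the torus,
    for cohorts with peaks near midnight).  Reported centroids are in
    hour coordinates in both cases (circular means for the torus
    metric).
    """
    if metric not in ("euclidean", "circular"):
        raise ClusteringError(f"unknown metric: {metric!r}")
    xy = np.array([[p.x, p.y] for p in points], dtype=float)
    if len(np.unique(xy, axis=0)) < k:
        raise ClusteringError(f"need >= {k} distinct points for k={k}")
    X = _torus_coords(xy) if metric == "circular" else xy
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    best = None
    for _ in range(n_init):
        centers, assign, inertia = _lloyd(X, k, rng, max_iter)
        if best is None or inertia < best[2]:
            best = (centers, assign, inertia)
    centers, assign, inertia = best

    if metric == "circular":
        # circular mean of member hour coordinates, per cluster
        hour_centers = np.empty((k, 2))
        for c in range(k):
            theta = xy[assign == c] * (2 * np.pi / PERIOD)
            mean_angle = np.arctan2(
                np.sin(theta).mean(axis=0), np.cos(theta).mean(axis=0)
            )
            hour_centers[c] = np.mod(mean_angle * PERIOD / (2 * np.pi), PERIOD)
        centers = hour_centers

    assignments = {p.person_id: int(c) for p, c in zip(points, assign)}
    logger.info("k-means k=%d: inertia=%.4f over %d points", k, inertia, len(points))
    return ClusterResult(k=k, centroids=centers, assignments=assignments, inertia=inertia)


def label_clusters(result: ClusterResult) -> ClusterResult:
    """Attach morningness/eveningness labels to a bipartite clustering.

    The cluster whose centroid has the earlier primary-peak coordinate
    (x) is morningness; labels follow centroids, not cluster indices.
    """
    if result.k != 2:
        raise ClusteringError("morningness/eveningness labels require k = 2")
    early = int(np.argmin(result.centroids[:, 0]))
    result.labels = {early: MORNINGNESS, 1 - early: EVENINGNESS}
    return result
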