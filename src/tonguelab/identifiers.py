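"""Clustering identifiers: picking the two informative clusters per image.

Of the k = 4 clusters of a tongue image, two carry the diagnostic
signal and become the SVM's features:

* the **maximum colour distance** cluster — the non-background cluster
  whose centroid lies farthest from Lab black (0, 0, 0); in clinical
  images this is the most chromatic (red/light-red) region, and
* the **maximum pixels' coverage area** cluster — the non-background
  cluster whose member pixels cover the largest area, measured by the
  tight bounding box w' x h' around them (a pixel-count alternative is
  available via ``metric="count"``); this region spreads across tip,
  bilateral edges and centre.

If one cluster wins both identifiers the coverage identifier is demoted
to its runner-up so the two always name distinct clusters: the distance
identifier is pinned to an explicit formula on a fixed reference point,
so it keeps its winner.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clustering import Cluster, ClusterSet
from .colorspace import BLACK, color_distance

__all__ = [
    "CoverageBox",
    "IdentifierSelection",
    "select_max_distance_cluster",
    "coverage_area",
    "select_max_coverage_cluster",
    "select_identifiers",
    "build_feature_vector",
]


@dataclass(frozen=True)
class CoverageBox:
    """Tight axis-aligned bounding box of a cluster's member pixels.

    ``area = w_prime * h_prime`` covers all nonzero (member) pixels,
    with ``w_prime`` <= image width and ``h_prime`` <= image height.
    """

    w_prime: int
    h_prime: int
    area: int
    n_nonzero: int


@dataclass(frozen=True)
class IdentifierSelection:
    max_distance_cluster_id: int
    max_coverage_cluster_id: int
    distance_value: float
    coverage: CoverageBox
    #: True when the coverage winner collided with the distance winner
    #: and the runner-up was substituted.
    collision: bool


def select_max_distance_cluster(cs: ClusterSet) -> tuple[int, float]:
    """Non-background cluster with the largest centroid distance from black.

    Ties break to the lowest cluster id.
    """
    candidates = cs.non_background()
    if len(candidates) < 2:
        raise ValueError("need at least 2 non-background clusters")
    best_id, best_d = None, -np.inf
    for c in sorted(candidates, key=lambda c: c.id):
        d = color_distance(c.centroid, BLACK)
        if d > best_d:
            best_id, best_d = c.id, d
    return best_id, float(best_d)


def coverage_area(c: Cluster, image_w: int, image_h: int) -> CoverageBox:
    """Bounding-box coverage of a cluster's pixels.

    Width/height are inclusive pixel extents (a cluster whose members
    span columns 0..2 has w' = 3).
    """
    rows, cols = np.nonzero(c.mask)
    if rows.size == 0:
        raise ValueError(f"cluster {c.id} has no member pixels")
    h_prime = int(rows.max() - rows.min() + 1)
    w_prime = int(cols.max() - cols.min() + 1)
    if w_prime > image_w or h_prime > image_h:
        raise ValueError("cluster mask exceeds stated image dimensions")
    return CoverageBox(w_prime=w_prime, h_prime=h_prime,
                       area=w_prime * h_prime, n_nonzero=int(rows.size))


def select_max_coverage_cluster(
    cs: ClusterSet,
    image_w: int,
    image_h: int,
    exclude_id: int | None = None,
    metric: str = "bbox",
) -> tuple[int, CoverageBox, bool]:
    """Non-background cluster with the largest coverage.

    ``metric="bbox"`` ranks by bounding-box area, ``"count"`` by member
    pixel count.  Ties break to the lowest id.  If the winner equals
    ``exclude_id`` (the max-distance winner), the runner-up is returned
    and the collision flag set.
    """
    if metric not in ("bbox", "count"):
        raise ValueError(f"unknown coverage metric {metric!r}")
    candidates = cs.non_background()
    if len(candidates) < 2:
        raise ValueError("need at least 2 non-background clusters")

    scored: list[tuple[int, CoverageBox]] = []
    for c in sorted(candidates, key=lambda c: c.id):
        if c.n_pixels == 0:
            continue
        scored.append((c.id, coverage_area(c, image_w, image_h)))
    key = (lambda t: t[1].area) if metric == "bbox" else (lambda t: t[1].n_nonzero)
    scored.sort(key=lambda t: (-key(t), t[0]))

    winner_id, winner_box = scored[0]
    if exclude_id is not None and winner_id == exclude_id:
        if len(scored) < 2:
            raise ValueError("no runner-up cluster available after collision")
        runner_id, runner_box = scored[1]
        return runner_id, runner_box, True
    return winner_id, winner_box, False


def select_identifiers(
    cs: ClusterSet, image_w: int, image_h: int, metric: str = "bbox"
) -> IdentifierSelection:
    """Run both identifier rules and resolve collisions."""
    dist_id, dist_val = select_max_distance_cluster(cs)
    cov_id, box, collided = select_max_coverage_cluster(
        cs, image_w, image_h, exclude_id=dist_id, metric=metric
    )
    return IdentifierSelection(
        max_distance_cluster_id=dist_id,
        max_coverage_cluster_id=cov_id,
        distance_value=dist_val,
        coverage=box,
        collision=collided,
    )


def build_feature_vector(
    sel: IdentifierSelection, cs: ClusterSet, mode: str = "image"
) -> np.ndarray:
    """Assemble SVM features from the two identifier clusters.

    ``mode="image"`` (default): a single 6-vector, the mean Lab colour
    of the max-distance cluster followed by that of the max-coverage
    cluster — one training instance per image.

    ``mode="instance"``: a (2, 3) array, one 3-vector row per
    identifier cluster — two training instances per image (N images
    give 2N instances; 300 images give the 600-instance accounting).
    """
    d = cs[sel.max_distance_cluster_id].mean_color
    c = cs[sel.max_coverage_cluster_id].mean_color
    if mode == "image":
        return np.concatenate([d, c])
    if mode == "instance":
        return np.vstack([d, c])
    raise ValueError(f"unknown feature mode {mode!r}")
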