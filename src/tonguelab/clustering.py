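"""k-means partitioning of a tongue image's pixels in CIELAB space.

With k = 4 the clusters of a typical post-segmentation tongue image are
the black background, a deep-red region, a red/light-red region and a
transitional region.  All pixels (background included) are clustered by
default and the background cluster is identified afterwards as the one
whose centroid lies nearest Lab black; set ``cluster_background=False``
to cluster foreground pixels only (k-1 colour clusters plus a synthetic
exact-black background cluster, so the partition contract is unchanged).

The heavy lifting is scikit-learn's Lloyd k-means with k-means++
seeding; determinism for a fixed seed is part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .colorspace import BLACK, LabImage, centroid_distance

__all__ = ["Cluster", "ClusterSet", "kmeans_lab", "identify_background"]


@dataclass(frozen=True)
class Cluster:
    """One k-means cluster of image pixels.

    ``centroid`` is the converged k-means centre; ``mean_color`` is the
    mean Lab value over member pixels.  At convergence the two coincide
    (to solver tolerance) but both are kept because downstream rules
    pin one or the other: the distance-from-black identifier uses the
    centroid, the colour-range rules use the mean colour.
    """

    id: int
    centroid: np.ndarray
    mean_color: np.ndarray
    mask: np.ndarray
    n_pixels: int


@dataclass(frozen=True)
class ClusterSet:
    clusters: list[Cluster]
    k: int
    background_id: int
    inertia: float

    def __getitem__(self, cluster_id: int) -> Cluster:
        for c in self.clusters:
            if c.id == cluster_id:
                return c
        raise KeyError(cluster_id)

    def non_background(self) -> list[Cluster]:
        return [c for c in self.clusters if c.id != self.background_id]


def _build_clusters(lab: np.ndarray, assignment: np.ndarray,
                    centroids: np.ndarray) -> list[Cluster]:
    clusters = []
    for cid in range(len(centroids)):
        mask = assignment == cid
        n = int(mask.sum())
        mean = lab[mask].mean(axis=0) if n else centroids[cid].copy()
        clusters.append(
            Cluster(id=cid, centroid=centroids[cid].copy(),
                    mean_color=mean, mask=mask, n_pixels=n)
        )
    return clusters


def kmeans_lab(
    image: LabImage,
    k: int = 4,
    seed: int = 0,
    n_init: int = 5,
    max_iter: int = 300,
    tol: float = 1e-4,
    cluster_background: bool = True,
) -> ClusterSet:
    """Cluster an image's pixels into ``k`` clusters in Lab space.

    Runs Lloyd k-means (Euclidean metric on (L*, a*, b*)) with
    k-means++ seeding and ``n_init`` restarts, keeping the restart with
    minimal inertia.  Deterministic for a fixed ``seed``.

    Parameters
    ----------
    cluster_background:
        If ``True`` (default) every pixel is clustered and the
        background cluster is found afterwards.  If ``False``, only
        foreground pixels are clustered (into ``k - 1`` clusters) and
        an exact-black background cluster is appended, preserving the
        partition invariant.

    Raises
    ------
    ValueError
        If ``k < 2`` or the image has fewer distinct pixel values than
        the number of colour clusters requested.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")

    lab = image.lab
    if cluster_background:
        data = lab.reshape(-1, 3)
        n_clusters = k
    else:
        data = lab[image.foreground_mask]
        n_clusters = k - 1

    if len(np.unique(data, axis=0)) < n_clusters:
        raise ValueError(
            f"image has fewer than {n_clusters} distinct pixel values; "
            "cannot form that many clusters"
        )

    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=n_init,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    ).fit(data)

    if cluster_background:
        assignment = km.labels_.reshape(lab.shape[:2])
        clusters = _build_clusters(lab, assignment, km.cluster_centers_)
        inertia = float(km.inertia_)
        cs = ClusterSet(clusters=clusters, k=k, background_id=0, inertia=inertia)
        bg = identify_background(cs)
        return ClusterSet(clusters=clusters, k=k, background_id=bg, inertia=inertia)

    # Foreground-only mode: colour clusters get ids 0..k-2, the synthetic
    # background cluster id k-1.
    assignment = np.full(lab.shape[:2], n_clusters, dtype=int)
    assignment[image.foreground_mask] = km.labels_
    centroids = np.vstack([km.cluster_centers_, BLACK])
    clusters = _build_clusters(lab, assignment, centroids)
    return ClusterSet(clusters=clusters, k=k, background_id=n_clusters,
                      inertia=float(km.inertia_))


def identify_background(cs: ClusterSet) -> int:
    """Id of the cluster whose centroid is nearest Lab black (0, 0, 0).

    Ties are broken by lowest cluster id (guaranteed by scanning in id
    order with a strict improvement test).
    """
    best_id, best_d = None, np.inf
    for c in sorted(cs.clusters, key=lambda c: c.id):
        d = centroid_distance(c.centroid, BLACK)
        if d < best_d:
            best_id, best_d = c.id, d
    assert best_id is not None
    return best_id
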