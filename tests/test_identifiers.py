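"""Identifier selection: max distance from black, bounding-box coverage,
collision demotion, and the feature vectors built from the winners."""

import numpy as np
import pytest

from tonguelab import (
    Cluster,
    ClusterSet,
    build_feature_vector,
    coverage_area,
    kmeans_lab,
    make_tongue_image,
    rgb_to_lab,
    select_identifiers,
    select_max_coverage_cluster,
    select_max_distance_cluster,
)


def _make_cluster(cid, centroid, mask, mean=None):
    mask = np.asarray(mask, dtype=bool)
    return Cluster(
        id=cid,
        centroid=np.asarray(centroid, float),
        mean_color=np.asarray(mean if mean is not None else centroid, float),
        mask=mask,
        n_pixels=int(mask.sum()),
    )


def _cluster_set(clusters, background_id=0):
    return ClusterSet(clusters=clusters, k=len(clusters),
                      background_id=background_id, inertia=0.0)


def _random_cluster_set(rng, shape=(12, 12), k=4):
    assignment = rng.integers(0, k, size=shape)
    clusters = [
        _make_cluster(i, rng.uniform(0, 80, 3), assignment == i) for i in range(k)
    ]
    return _cluster_set(clusters, background_id=0)


# ------------------------------------------------------- distance winner
def test_max_distance_is_the_farthest_centroid_from_black():
    mask = np.ones((2, 2), bool)
    cs = _cluster_set([
        _make_cluster(0, (0, 0, 0), mask),
        _make_cluster(1, (55, 33, 8), mask),
        _make_cluster(2, (35, 20, 2), mask),
        _make_cluster(3, (60, 25, 17), mask),
    ])
    cid, dist = select_max_distance_cluster(cs)
    assert cid == 3
    assert dist == pytest.approx(np.sqrt(60**2 + 25**2 + 17**2))


def test_max_distance_tie_breaks_to_lowest_id():
    mask = np.ones((2, 2), bool)
    cs = _cluster_set([
        _make_cluster(0, (0, 0, 0), mask),
        _make_cluster(1, (30, 40, 0), mask),
        _make_cluster(2, (30, 0, 40), mask),
    ])
    assert select_max_distance_cluster(cs)[0] == 1


def test_max_distance_matches_brute_force(rng):
    for _ in range(100):
        cs = _random_cluster_set(rng)
        cid, dist = select_max_distance_cluster(cs)
        # brute-force loop over the distance-from-black formula
        best_id, best = None, -1.0
        for c in cs.non_background():
            d = np.sqrt((c.centroid**2).sum())
            if d > best:
                best_id, best = c.id, d
        assert cid == best_id and dist == pytest.approx(best)


# ------------------------------------------------------------- coverage
def test_coverage_box_of_two_corner_pixels():
    mask = np.zeros((6, 5), bool)
    mask[0, 0] = mask[3, 2] = True
    box = coverage_area(_make_cluster(1, (1, 1, 1), mask), image_w=5, image_h=6)
    assert (box.w_prime, box.h_prime, box.area, box.n_nonzero) == (3, 4, 12, 2)


def test_full_image_cluster_saturates_coverage():
    mask = np.ones((7, 9), bool)
    box = coverage_area(_make_cluster(1, (1, 1, 1), mask), image_w=9, image_h=7)
    assert box.area == 63 and (box.w_prime, box.h_prime) == (9, 7)


def test_coverage_matches_minmax_scan_oracle(rng):
    for _ in range(100):
        mask = rng.random((10, 14)) < 0.2
        if not mask.any():
            mask[rng.integers(10), rng.integers(14)] = True
        box = coverage_area(_make_cluster(1, (1, 1, 1), mask), image_w=14, image_h=10)
        rows = [r for r in range(10) if mask[r].any()]
        cols = [c for c in range(14) if mask[:, c].any()]
        assert box.h_prime == rows[-1] - rows[0] + 1
        assert box.w_prime == cols[-1] - cols[0] + 1
        assert box.area == box.w_prime * box.h_prime
        assert box.n_nonzero == mask.sum()
        assert box.area >= box.n_nonzero


def test_empty_cluster_coverage_rejected():
    with pytest.raises(ValueError):
        coverage_area(_make_cluster(1, (1, 1, 1), np.zeros((3, 3), bool)), 3, 3)


def test_spanning_cluster_beats_tip_cluster():
    span = np.zeros((10, 10), bool); span[1:9, 1:9] = True
    tip = np.zeros((10, 10), bool); tip[7:9, 4:6] = True
    cs = _cluster_set([
        _make_cluster(0, (0, 0, 0), ~(span | tip)),
        _make_cluster(1, (40, 20, 5), span),
        _make_cluster(2, (50, 38, 9), tip),
    ])
    cid, box, collided = select_max_coverage_cluster(cs, 10, 10)
    assert cid == 1 and not collided and box.area == 64


def test_collision_demotes_coverage_to_runner_up():
    big = np.zeros((10, 10), bool); big[0:9, 0:9] = True
    small = np.zeros((10, 10), bool); small[2:5, 2:5] = True
    cs = _cluster_set([
        _make_cluster(0, (0, 0, 0), ~(big | small)),
        _make_cluster(1, (70, 40, 20), big),    # wins both identifiers
        _make_cluster(2, (30, 10, 2), small),
    ])
    sel = select_identifiers(cs, 10, 10)
    assert sel.max_distance_cluster_id == 1
    assert sel.max_coverage_cluster_id == 2
    assert sel.collision


def test_coverage_matches_brute_force_scan(rng):
    for _ in range(100):
        cs = _random_cluster_set(rng)
        cid, box, _ = select_max_coverage_cluster(cs, 12, 12)
        best_id, best_area = None, -1
        for c in cs.non_background():  # id order, so ties keep the lowest id
            if c.n_pixels == 0:
                continue
            b = coverage_area(c, 12, 12)
            if b.area > best_area:
                best_id, best_area = c.id, b.area
        assert cid == best_id


def test_count_metric_ranks_by_pixel_count():
    sparse = np.zeros((10, 10), bool)
    sparse[0, 0] = sparse[9, 9] = True          # tiny count, huge box
    dense = np.zeros((10, 10), bool); dense[4:8, 4:8] = True
    cs = _cluster_set([
        _make_cluster(0, (0, 0, 0), ~(sparse | dense)),
        _make_cluster(1, (40, 20, 5), sparse),
        _make_cluster(2, (30, 10, 2), dense),
    ])
    assert select_max_coverage_cluster(cs, 10, 10, metric="bbox")[0] == 1
    assert select_max_coverage_cluster(cs, 10, 10, metric="count")[0] == 2


# -------------------------------------------------------------- features
def test_feature_vector_modes():
    mask = np.ones((2, 2), bool)
    cs = _cluster_set([
        _make_cluster(0, (0, 0, 0), mask),
        _make_cluster(1, (60, 25, 17), mask),
        _make_cluster(2, (40, 35, 5), mask),
    ])
    sel = select_identifiers(cs, 2, 2)
    assert sel.max_distance_cluster_id == 1  # |(60,25,17)| > |(40,35,5)|
    img_vec = build_feature_vector(sel, cs, mode="image")
    assert np.array_equal(img_vec, [60, 25, 17, 40, 35, 5])
    inst = build_feature_vector(sel, cs, mode="instance")
    assert inst.shape == (2, 3)
    assert np.array_equal(inst, [[60, 25, 17], [40, 35, 5]])
    with pytest.raises(ValueError):
        build_feature_vector(sel, cs, mode="bogus")


def test_feature_entries_equal_mask_recomputed_means(small_params):
    img = rgb_to_lab(make_tongue_image("red", small_params, seed=21).rgb)
    cs = kmeans_lab(img, k=4, seed=0)
    sel = select_identifiers(cs, img.width, img.height)
    vec = build_feature_vector(sel, cs, mode="image")
    d = img.lab[cs[sel.max_distance_cluster_id].mask].mean(axis=0)
    c = img.lab[cs[sel.max_coverage_cluster_id].mask].mean(axis=0)
    assert np.allclose(vec, np.concatenate([d, c]), atol=1e-9)


def test_selected_clusters_distinct_and_not_background(small_params):
    for i, cls in enumerate(["light_red", "red", "deep_red"] * 5):
        syn = make_tongue_image(cls, small_params, seed=300 + i)
        lab = rgb_to_lab(syn.rgb)
        cs = kmeans_lab(lab, k=4, seed=0)
        sel = select_identifiers(cs, lab.width, lab.height)
        assert sel.max_distance_cluster_id != sel.max_coverage_cluster_id
        assert cs.background_id not in (
            sel.max_distance_cluster_id, sel.max_coverage_cluster_id
        )


def test_deep_red_coverage_cluster_is_less_chromatic(small_params):
    """On deep-red images the max-coverage cluster's mean colour has
    lower a* and b* than the max-distance cluster's (the coverage
    identifier finds the darker, least-red region)."""
    hits = 0
    n = 40
    for i in range(n):
        syn = make_tongue_image("deep_red", small_params, seed=500 + i)
        lab = rgb_to_lab(syn.rgb)
        cs = kmeans_lab(lab, k=4, seed=0)
        sel = select_identifiers(cs, lab.width, lab.height)
        d = cs[sel.max_distance_cluster_id].mean_color
        c = cs[sel.max_coverage_cluster_id].mean_color
        hits += (c[1] < d[1]) and (c[2] < d[2])
    assert hits / n >= 0.95


def test_instance_mode_emits_two_rows_per_image(small_params):
    rows = 0
    for i in range(4):
        syn = make_tongue_image("red", small_params, seed=700 + i)
        lab = rgb_to_lab(syn.rgb)
        cs = kmeans_lab(lab, k=4, seed=0)
        sel = select_identifiers(cs, lab.width, lab.height)
        rows += build_feature_vector(sel, cs, mode="instance").shape[0]
    assert rows == 8
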