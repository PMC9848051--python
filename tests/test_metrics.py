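import numpy as np
import pytest
from scipy.spatial.distance import cdist

from neuminer.metrics import (evaluate_pair, nearest_distances,
                              path_length_ratio, pds_metrics,
                              recall_by_intensity, sd_metrics,
                              self_crossing_count, ssd_metrics, voxel_recall)
from neuminer.swc import SwcNode, SwcTree

from conftest import random_tree


def brute_nearest(a, b):
    return cdist(a, b).min(axis=1)


def test_nearest_identity_and_345(rng):
    pts = rng.random((20, 3))
    assert np.allclose(nearest_distances(pts, pts), 0)
    assert nearest_distances([[0, 0, 0]], [[3, 4, 0]])[0] == pytest.approx(5.0)


def test_nearest_empty_reference_raises():
    with pytest.raises(ValueError):
        nearest_distances(np.zeros((2, 3)), np.zeros((0, 3)))


def test_nearest_matches_brute_force(rng):
    a, b = rng.random((200, 3)) * 50, rng.random((150, 3)) * 50
    assert np.allclose(nearest_distances(a, b), brute_nearest(a, b))


def _point_tree(*pts):
    nodes = [SwcNode(1, 1, *pts[0], 1, -1)]
    for i, p in enumerate(pts[1:], start=2):
        nodes.append(SwcNode(i, 3, *p, 1, 1))
    return SwcTree(nodes)


def test_sd_identical_trees_zero(rng):
    t = random_tree(rng, 20)
    assert sd_metrics(t, t) == (0, 0, 0)


def test_sd_single_points_five_apart():
    a = _point_tree((0, 0, 0))
    b = _point_tree((3, 4, 0))
    assert sd_metrics(a, b) == (5, 5, 5)


def test_sd_directionality_on_pruned_copy(rng):
    gold = random_tree(rng, 40)
    keep = gold.subtree_ids(1) - gold.subtree_ids(25)
    recon = gold.without(gold.subtree_ids(25))
    sd12, sd21, _ = sd_metrics(gold, recon)
    assert sd21 == pytest.approx(0.0, abs=1e-12)
    assert sd12 > 0


def test_sd_symmetry_and_translation_invariance(rng):
    a, b = random_tree(rng, 25), random_tree(rng, 30)
    assert sd_metrics(a, b)[2] == pytest.approx(sd_metrics(b, a)[2])
    a2, b2 = a.translated(7, -3, 11), b.translated(7, -3, 11)
    assert sd_metrics(a2, b2) == pytest.approx(sd_metrics(a, b))


def test_ssd_thresholding():
    # gold points at distances {1, 5} from the reconstruction point set
    gold = _point_tree((0, 0, 0), (0, 0, 1))
    recon = _point_tree((0, 0, 1), (5, 0, 0))
    d = nearest_distances(gold.coordinates(), recon.coordinates())
    assert sorted(d.tolist()) == [0.0, 1.0]
    ssd12, _, _ = ssd_metrics(gold, recon, resample=False)
    assert ssd12 == 0.0  # nothing beyond 2 voxels
    far = _point_tree((0, 0, 0), (9, 0, 0))
    ssd12, _, _ = ssd_metrics(far, _point_tree((0, 0, 1)), resample=False)
    assert ssd12 == pytest.approx(np.hypot(9, 1))  # only the >2 distance kept


def test_pds_fraction():
    gold = _point_tree((0, 0, 0), (9, 0, 0))
    recon = _point_tree((0, 0, 0))
    pds12, _, _ = pds_metrics(gold, recon, resample=False)
    assert pds12 == pytest.approx(0.5)


def test_distance_metrics_match_oracle_on_random_clouds(rng):
    for _ in range(10):
        a = random_tree(rng, int(rng.integers(5, 40)))
        b = random_tree(rng, int(rng.integers(5, 40)))
        pa, pb = a.coordinates(), b.coordinates()
        d12, d21 = brute_nearest(pa, pb), brute_nearest(pb, pa)
        sd12, sd21, sd = sd_metrics(a, b, resample=False)
        assert sd12 == pytest.approx(d12.mean())
        assert sd21 == pytest.approx(d21.mean())
        assert sd == pytest.approx((d12.mean() + d21.mean()) / 2)
        ssd12 = ssd_metrics(a, b, resample=False)[0]
        big = d12[d12 > 2]
        assert ssd12 == pytest.approx(big.mean() if len(big) else 0.0)
        assert pds_metrics(a, b, resample=False)[0] == \
            pytest.approx((d12 > 2).mean())


def test_pruning_monotonicity(rng):
    """Nested prunings of the reconstruction: sd12 never decreases, sd21
    never increases (it stays 0 for subsets of the gold)."""
    gold = random_tree(rng, 60)
    prunable = [n.id for n in gold
                if n.id != 1 and not gold.children(n.id)]
    recon = gold
    last_sd12 = -1.0
    for leaf in prunable[:6]:
        if leaf not in {n.id for n in recon}:
            continue
        sd12, sd21, _ = sd_metrics(gold, recon)
        assert sd12 >= last_sd12 - 1e-12
        assert sd21 == pytest.approx(0.0, abs=1e-12)
        last_sd12 = sd12
        recon = recon.without(recon.subtree_ids(leaf))


def test_recall_by_intensity_constructed_case():
    image = np.zeros((8, 32, 32))
    image[2, 5, 5] = 10 / 255    # weak gold point
    image[2, 20, 20] = 50 / 255  # bright gold point
    gold = _point_tree((5, 5, 2), (20, 20, 2))
    recon = _point_tree((20, 20, 2))  # covers only the bright point
    # step larger than the segment keeps exactly the two annotated points
    per_bin, weak = recall_by_intensity(gold, recon, image, step=30)
    assert weak == 0.0
    assert per_bin["40-80"] == 1.0


def test_recall_perfect_when_recon_equals_gold(rng, small_scene):
    per_bin, weak = recall_by_intensity(small_scene.gold, small_scene.gold,
                                        small_scene.image)
    for v in per_bin.values():
        assert np.isnan(v) or v == 1.0
    assert weak == 1.0 or np.isnan(weak)


def test_path_length_ratio_cases(rng):
    t = random_tree(rng, 30)
    assert path_length_ratio(t, t) == pytest.approx(1.0)
    doubled = SwcTree([SwcNode(n.id, n.type_code, 2 * n.x, 2 * n.y, 2 * n.z,
                               n.radius, n.parent_id) for n in t])
    assert path_length_ratio(t, doubled) == pytest.approx(2.0)
    pruned = t.without(t.subtree_ids(15))
    assert path_length_ratio(t, pruned) == pytest.approx(
        pruned.total_length() / t.total_length())


def crossing_oracle(tree, soma_exclusion, generation_exclusion, dist_thresh):
    """All-pairs loop with the same exclusions."""
    def anc(nid):
        out = {nid}
        cur = tree.node(nid)
        for _ in range(generation_exclusion):
            if cur.parent_id == -1:
                break
            cur = tree.node(cur.parent_id)
            out.add(cur.id)
        return out

    root = tree.root.xyz
    nodes = [n for n in tree if np.linalg.norm(n.xyz - root) >= soma_exclusion]
    count = 0
    for i in range(len(nodes)):
        for j in range(i + 1, len(nodes)):
            if np.linalg.norm(nodes[i].xyz - nodes[j].xyz) < dist_thresh:
                if anc(nodes[i].id).isdisjoint(anc(nodes[j].id)):
                    count += 1
    return count


def test_straight_neurite_has_no_self_crossings(straight_tree):
    assert self_crossing_count(straight_tree, soma_exclusion=0,
                               generation_exclusion=10) == 0


def test_engineered_crossing_detected():
    # two branches leaving the soma in opposite directions and meeting
    # far away, passing within 0.5 voxels
    nodes = [SwcNode(1, 1, 0, 0, 0, 2, -1)]
    nid = 2
    parent = 1
    for i in range(1, 61):  # branch A: along +x then bends to (60, 30)
        y = 0 if i <= 30 else (i - 30)
        nodes.append(SwcNode(nid, 3, i, y, 0, 1, parent))
        parent = nid
        nid += 1
    parent = 1
    for i in range(1, 61):  # branch B: along +y then bends to meet A
        x = 0 if i <= 30 else (i - 30)
        y = i if i <= 30 else 30
        nodes.append(SwcNode(nid, 3, x + 30.2, y, 0, 1, parent))
        parent = nid
        nid += 1
    tree = SwcTree(nodes)
    count = self_crossing_count(tree, soma_exclusion=20,
                                generation_exclusion=10, dist_thresh=1.0)
    assert count >= 1
    assert count == crossing_oracle(tree, 20, 10, 1.0)


def test_self_crossing_matches_oracle_on_random_trees(rng):
    for _ in range(8):
        t = random_tree(rng, 35, spread=10.0)
        got = self_crossing_count(t, soma_exclusion=5, generation_exclusion=4,
                                  dist_thresh=2.0)
        assert got == crossing_oracle(t, 5, 4, 2.0)


def test_voxel_recall_strata(small_scene):
    prob = np.ones(small_scene.image.shape)
    out = voxel_recall(small_scene.gold, prob, small_scene.image)
    assert out["overall"] == 1.0 and out["weak"] == 1.0
    out0 = voxel_recall(small_scene.gold, np.zeros_like(prob),
                        small_scene.image)
    assert out0["overall"] == 0.0


def test_evaluate_pair_self_comparison(rng, small_scene):
    report = evaluate_pair(small_scene.gold, small_scene.gold,
                           image=small_scene.image)
    assert report.sd == report.sd12 == report.sd21 == 0
    assert report.pds == 0 and report.ssd == 0
    assert report.path_length_ratio == pytest.approx(1.0)
    assert report.weak_recall == 1.0 or np.isnan(report.weak_recall)
    assert report.sd == pytest.approx((report.sd12 + report.sd21) / 2)
    d = report.to_dict()
    assert "recall_by_intensity" in d and "sd" in d
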