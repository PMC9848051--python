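import numpy as np
import pytest

from neuminer.fnm import (build_weight_map, extract_false_negatives,
                          weighted_voxel_loss)
from neuminer.nn.losses import (cross_entropy_map, deep_supervision_loss,
                                dice_loss, head_loss, maxpool_label, softmax)


def fn_oracle(f, p):
    out = np.zeros(f.shape, dtype=bool)
    for idx in np.ndindex(f.shape):
        out[idx] = f[idx] > 0 and p[idx] < 0.5
    return out


def weighted_loss_oracle(losses, weights):
    total = 0.0
    n = 0
    for idx in np.ndindex(losses.shape):
        total += weights[idx] * losses[idx]
        n += 1
    return total / n


def test_fn_definition_cases():
    f = np.array([1.0, 1.0, 0.0])
    p = np.array([0.4, 0.9, 0.1])
    assert extract_false_negatives(f, p).tolist() == [True, False, False]


def test_fn_empty_when_prediction_perfect():
    f = np.array([1.0, 0.0, 1.0])
    p = np.array([1.0, 0.0, 1.0])
    assert not extract_false_negatives(f, p).any()


def test_fn_shape_mismatch_raises():
    with pytest.raises(ValueError):
        extract_false_negatives(np.zeros(3), np.zeros(4))


def test_fn_matches_per_voxel_oracle(rng):
    f = (rng.random((16, 16, 16)) < 0.2).astype(float)
    p = rng.random((16, 16, 16))
    assert np.array_equal(extract_false_negatives(f, p), fn_oracle(f, p))


def test_weight_map_values():
    fn = np.array([True, False])
    w = build_weight_map(fn, 1.5)
    assert w.tolist() == [1.5, 1.0]
    assert build_weight_map(np.zeros(4, dtype=bool)).tolist() == [1.0] * 4


def test_false_positives_keep_unit_weight():
    f = np.array([0.0, 1.0])
    p = np.array([0.9, 0.4])  # first voxel is a false positive
    w = build_weight_map(extract_false_negatives(f, p), 1.5)
    assert w[0] == 1.0 and w[1] == 1.5


def test_weight_map_rejects_wfn_below_one():
    with pytest.raises(ValueError):
        build_weight_map(np.array([True]), 0.5)


def test_weighted_loss_unit_weights_is_mean(rng):
    losses = rng.random((2, 1, 4, 4, 4))
    assert weighted_voxel_loss(losses, np.ones_like(losses)) == \
        pytest.approx(losses.mean())


def test_weighted_loss_single_voxel():
    assert weighted_voxel_loss(np.array([0.2]), np.array([1.5])) == \
        pytest.approx(0.3)


def test_weighted_loss_matches_nested_loop_oracle(rng):
    losses = rng.random((2, 1, 4, 5, 6))
    weights = np.where(rng.random(losses.shape) < 0.3, 1.5, 1.0)
    assert weighted_voxel_loss(losses, weights) == \
        pytest.approx(weighted_loss_oracle(losses, weights))


def test_dice_perfect_and_inverted(rng):
    f = (rng.random((4, 4, 4)) < 0.4).astype(float)
    assert dice_loss(f, f) == pytest.approx(0.0, abs=1e-4)
    assert dice_loss(1 - f, f) == pytest.approx(1.0, abs=1e-4)


def test_dice_matches_hand_formula(rng):
    p = rng.random((4, 4, 4))
    f = (rng.random((4, 4, 4)) < 0.4).astype(float)
    eps = 1e-5
    expected = 1 - (2 * (p * f).sum() + eps) / (p.sum() + f.sum() + eps)
    assert dice_loss(p, f) == pytest.approx(expected)


def test_head_loss_perfect_prediction_fnm_noop(rng):
    """With a perfect prediction, FN is empty so FNM-weighted loss equals
    the unweighted loss exactly."""
    f = (rng.random((1, 8, 8, 8)) < 0.3).astype(np.float64)
    logits = np.stack([(1 - f) * 20.0, f * 20.0], axis=1) - 10.0
    loss_fnm, _, stats = head_loss(logits, f, wfn=1.5, use_fnm=True)
    loss_plain, _, _ = head_loss(logits, f, use_fnm=False)
    assert stats["n_fn"] == 0
    assert loss_fnm == loss_plain
    assert loss_fnm == pytest.approx(0.0, abs=1e-3)


def test_monotone_emphasis_iff_fn_nonempty(rng):
    f = (rng.random((1, 8, 8, 8)) < 0.3).astype(np.float64)
    logits = rng.normal(size=(1, 2, 8, 8, 8))
    losses = []
    for wfn in (1.0, 1.5, 2.0):
        _, _, st = head_loss(logits, f, wfn=wfn, use_fnm=True)
        losses.append(st["ce"])
    assert losses[0] < losses[1] < losses[2]
    # with a perfect prediction no FN exist, so wfn has no effect
    perfect = np.stack([(1 - f) * 20.0, f * 20.0], axis=1) - 10.0
    ces = [head_loss(perfect, f, wfn=wfn)[2]["ce"] for wfn in (1.0, 2.0)]
    assert ces[0] == ces[1]


def test_deep_supervision_aux_weight_zero(rng):
    f = (rng.random((1, 8, 8, 8)) < 0.3).astype(np.float64)
    final = rng.normal(size=(1, 2, 8, 8, 8))
    aux = rng.normal(size=(1, 2, 4, 4, 4))
    total, grads, _ = deep_supervision_loss((final, aux), f,
                                            head_weights=(1.0, 0.0))
    expected, _, _ = head_loss(final, f)
    assert total == pytest.approx(expected)
    assert np.all(grads[1] == 0)


def test_deep_supervision_single_head(rng):
    f = (rng.random((1, 8, 8, 8)) < 0.3).astype(np.float64)
    final = rng.normal(size=(1, 2, 8, 8, 8))
    total, _, _ = deep_supervision_loss((final,), f, head_weights=(1.0,))
    assert total == pytest.approx(head_loss(final, f)[0])


def test_maxpool_label_preserves_single_voxel_fiber():
    lab = np.zeros((1, 4, 4, 4))
    lab[0, 1, 2, 3] = 1
    pooled = maxpool_label(lab, 2)
    assert pooled.shape == (1, 2, 2, 2)
    assert pooled.sum() == 1


def test_softmax_rows_sum_to_one(rng):
    z = rng.normal(size=(2, 2, 3, 3, 3))
    assert np.allclose(softmax(z, axis=1).sum(axis=1), 1.0)
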