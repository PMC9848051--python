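import numpy as np
import pytest

from neuminer.inference import predict_volume
from neuminer.nn import build_network, deep_supervision_loss
from neuminer.nn.layers import Conv3d, InstanceNorm3d, MaxPool3d, Upsample3d


def test_output_shape_contract():
    net = build_network(levels=2, base_channels=4, seed=0)
    x = np.zeros((1, 1, 16, 16, 16), dtype=np.float32)
    final, aux = net.forward(x)
    assert final.shape == (1, 2, 16, 16, 16)
    assert aux.shape == (1, 2, 8, 8, 8)


def test_three_level_aux_resolution():
    net = build_network(levels=3, base_channels=4, seed=0)
    final, aux = net.forward(np.zeros((1, 1, 16, 16, 16), dtype=np.float32))
    assert final.shape[2:] == (16, 16, 16)
    assert aux.shape[2:] == (8, 8, 8)


def test_input_not_multiple_of_stride_raises():
    net = build_network(levels=3, base_channels=4, seed=0)
    with pytest.raises(ValueError):
        net.forward(np.zeros((1, 1, 10, 10, 10), dtype=np.float32))


def test_tiny_parameter_count_regression():
    net = build_network(levels=2, base_channels=8)
    assert net.n_parameters() <= 17876  # frozen from this architecture


def test_flip_shape_documented_nonproperty():
    """Flipping input and un-flipping output preserves shapes; exact
    equivariance is NOT guaranteed and not asserted."""
    net = build_network(levels=2, base_channels=4, seed=0)
    x = np.random.default_rng(0).random((1, 1, 8, 8, 8)).astype(np.float32)
    f1, _ = net.forward(x)
    f2, _ = net.forward(x[:, :, ::-1].copy())
    assert f2[:, :, ::-1].shape == f1.shape


def test_gradients_match_finite_differences(rng):
    """End-to-end float64 gradient check through every layer type."""
    net = build_network(levels=2, base_channels=2, seed=3)
    for p in net.params():
        p.value = p.value.astype(np.float64)
    x = rng.random((1, 1, 8, 8, 8))
    label = (rng.random((1, 8, 8, 8)) < 0.3).astype(np.float64)

    def loss():
        return deep_supervision_loss(net.forward(x), label, use_fnm=False)[:2]

    net.zero_grad()
    _, grads = loss()
    net.backward(*grads)
    eps = 1e-6
    for p in net.params()[::4]:
        flat = p.value.reshape(-1)
        gflat = p.grad.reshape(-1)
        for i in rng.choice(flat.size, size=min(2, flat.size), replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = loss()
            flat[i] = orig - eps
            lm, _ = loss()
            flat[i] = orig
            num = (lp - lm) / (2 * eps)
            assert abs(num - gflat[i]) < 1e-6 * max(1.0, abs(num))


def test_state_dict_round_trip():
    net = build_network(levels=2, base_channels=4, seed=0)
    other = build_network(levels=2, base_channels=4, seed=99)
    x = np.random.default_rng(1).random((1, 1, 8, 8, 8)).astype(np.float32)
    other.load_state_dict(net.state_dict())
    assert np.array_equal(net.forward(x)[0], other.forward(x)[0])


def test_maxpool_upsample_inverse_on_blocks():
    rng = np.random.default_rng(0)
    x = rng.random((1, 2, 4, 4, 4)).astype(np.float32)
    up = Upsample3d()
    pool = MaxPool3d()
    # pooling an upsampled volume recovers it exactly (blocks are constant)
    assert np.array_equal(pool.forward(up.forward(x)), x)


def test_instance_norm_standardizes(rng):
    layer = InstanceNorm3d(3)
    x = rng.normal(5.0, 2.0, size=(2, 3, 6, 6, 6))
    out = layer.forward(x)
    assert np.allclose(out.mean(axis=(2, 3, 4)), 0, atol=1e-6)
    assert np.allclose(out.std(axis=(2, 3, 4)), 1, atol=1e-3)


def test_conv_matches_direct_convolution(rng):
    """Oracle: direct triple-loop convolution on a tiny input."""
    conv = Conv3d(2, 3, 3, np.random.default_rng(0))
    x = rng.random((1, 2, 4, 4, 4)).astype(np.float32)
    out = conv.forward(x)
    w, b = conv.weight.value, conv.bias.value
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1), (1, 1)))
    expected = np.zeros((1, 3, 4, 4, 4))
    for co in range(3):
        for z in range(4):
            for y in range(4):
                for xx in range(4):
                    acc = 0.0
                    for ci in range(2):
                        for a in range(3):
                            for bb in range(3):
                                for cc in range(3):
                                    acc += (w[co, ci, a, bb, cc]
                                            * xp[0, ci, z + a, y + bb, xx + cc])
                    expected[0, co, z, y, xx] = acc + b[co]
    assert np.allclose(out, expected, atol=1e-5)


def test_predict_volume_range_and_single_tile():
    net = build_network(levels=2, base_channels=4, seed=0)
    vol = np.random.default_rng(2).random((16, 16, 16)).astype(np.float32)
    prob = predict_volume(net, vol, tile_xyz=(32, 32, 32))
    assert prob.shape == vol.shape
    assert prob.min() >= 0 and prob.max() <= 1


def test_predict_volume_single_tile_equals_forward_softmax():
    from neuminer.nn import softmax
    net = build_network(levels=2, base_channels=4, seed=0)
    vol = np.random.default_rng(3).random((16, 16, 16)).astype(np.float32)
    prob = predict_volume(net, vol, tile_xyz=(16, 16, 16))
    logits, _ = net.forward(vol[None, None])
    assert np.allclose(prob, softmax(logits, axis=1)[0, 1], atol=1e-6)


def test_predict_volume_tiled_roughly_consistent():
    # instance-norm statistics are computed per tile, so tiled and untiled
    # inference agree only approximately; exact agreement is not a property
    # of this architecture
    net = build_network(levels=2, base_channels=4, seed=0)
    vol = np.random.default_rng(3).random((32, 32, 32)).astype(np.float32)
    whole = predict_volume(net, vol, tile_xyz=(32, 32, 32))
    tiled = predict_volume(net, vol, tile_xyz=(16, 16, 16), overlap=0.5)
    assert np.abs(whole - tiled).mean() < 0.2
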