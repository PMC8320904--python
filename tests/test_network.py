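"""Architecture contracts: CReLU, gated residual units, shape/width
schedules, forward determinism, loss, and checkpoint round-trips."""

import math

import numpy as np
import pytest

from pixelbnn.network import (
    ConfigError,
    NetworkConfig,
    PixelBNN,
    build_network,
    crelu,
    load_checkpoint,
    save_checkpoint,
    segmentation_loss,
)
from pixelbnn.nn import autodiff as ad
from pixelbnn.nn.layers import GatedResNetUnit

TINY = NetworkConfig(base_features=4, num_stages=2, resnets_per_block=1)


class TestCRelu:
    def test_definition_on_signed_channels(self):
        x = np.array([[[[3.0, -2.0]]]])
        out = crelu(x)
        assert np.array_equal(out[0, 0, 0], [3.0, 0.0, 0.0, 2.0])

    def test_zero_input_doubles_channels_with_zeros(self):
        out = crelu(np.zeros((2, 4, 4, 5)))
        assert out.shape == (2, 4, 4, 10)
        assert not out.any()

    def test_halves_reconstruct_input_and_are_nonnegative(self):
        x = np.random.default_rng(0).standard_normal((2, 8, 8, 6))
        out = crelu(x)
        assert out.min() >= 0
        pos, neg = out[..., :6], out[..., 6:]
        assert np.allclose(pos - neg, x)


class TestGatedResNet:
    def test_shape_contract_preserved(self):
        rng = np.random.default_rng(0)
        unit = GatedResNetUnit(32, rng=rng)
        x1 = ad.Tensor(rng.standard_normal((1, 16, 16, 32)).astype(np.float32))
        x2 = ad.Tensor(rng.standard_normal((1, 16, 16, 32)).astype(np.float32))
        o1, o2 = unit(x1, x2)
        assert o1.shape == x1.shape and o2.shape == x2.shape

    def test_stream_shape_mismatch_raises(self):
        unit = GatedResNetUnit(8, rng=np.random.default_rng(0))
        x1 = ad.Tensor(np.zeros((1, 8, 8, 8), np.float32))
        x2 = ad.Tensor(np.zeros((1, 4, 4, 8), np.float32))
        with pytest.raises(ValueError):
            unit(x1, x2)

    def test_zero_weights_give_residual_identity(self):
        unit = GatedResNetUnit(8, rng=np.random.default_rng(0))
        for p in unit.parameters():
            p.data[...] = 0.0
        rng = np.random.default_rng(1)
        x1 = ad.Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
        x2 = ad.Tensor(rng.standard_normal((2, 8, 8, 8)).astype(np.float32))
        o1, o2 = unit(x1, x2)
        assert np.array_equal(o1.data, x1.data)
        assert np.array_equal(o2.data, x2.data)

    def test_gradient_reaches_both_streams(self):
        """Analytic gradients on one parameter per stream agree with central
        finite differences of the scalar loss."""
        rng = np.random.default_rng(0)
        unit = GatedResNetUnit(4, rng=rng)
        x1 = ad.Tensor(rng.standard_normal((1, 6, 6, 4)).astype(np.float32))
        x2 = ad.Tensor(rng.standard_normal((1, 6, 6, 4)).astype(np.float32))
        target = (rng.random((1, 6, 6, 8)) > 0.5).astype(np.float32)

        def scalar_loss():
            o1, o2 = unit(x1, x2)
            return ad.sigmoid_cross_entropy(ad.concat(o1, o2), target)

        loss = scalar_loss()
        loss.backward()
        for param in (unit.s1_conv1.weight, unit.s2_conv1.weight):
            assert param.grad is not None and np.abs(param.grad).max() > 0
            idx = np.unravel_index(np.abs(param.grad).argmax(), param.shape)
            analytic = param.grad[idx]
            eps, orig = 1e-2, param.data[idx]
            param.data[idx] = orig + eps
            hi = scalar_loss().item()
            param.data[idx] = orig - eps
            lo = scalar_loss().item()
            param.data[idx] = orig
            numeric = (hi - lo) / (2 * eps)
            assert numeric == pytest.approx(analytic, rel=0.1, abs=1e-4)


class TestBuildNetwork:
    def test_default_gated_resnet_count(self):
        model = build_network(NetworkConfig())
        assert model.num_gated_resnets() == 2 * 3 * 4 == 24

    def test_tiny_width_and_spatial_schedule(self):
        model = PixelBNN(TINY, seed=0)
        model.forward(np.zeros((1, 32, 32, 3), np.float32))
        trace = model.last_trace
        assert [s[3] for s in trace["encoder_blocks"]] == [4, 8]
        assert [s[1] for s in trace["encoder_blocks"]] == [32, 16]
        assert trace["after_downsample"][-1][1:] == (8, 8, 8)
        assert [s[3] for s in trace["decoder_blocks"]] == [8, 4]

    def test_indivisible_input_side_raises(self):
        model = PixelBNN(TINY, seed=0)
        with pytest.raises(ConfigError):
            model.forward(np.zeros((1, 30, 30, 3), np.float32))

    def test_checkpoint_roundtrip_preserves_outputs(self, tmp_path):
        model = PixelBNN(TINY, seed=3)
        x = np.random.default_rng(0).standard_normal((1, 16, 16, 3)).astype(np.float32)
        before = model.forward(x)
        path = tmp_path / "ckpt.npz"
        save_checkpoint(model, path, extra={"step": 1})
        loaded, extra = load_checkpoint(path)
        assert extra == {"step": 1}
        assert np.array_equal(loaded.forward(x), before)


class TestForward:
    def test_inference_is_deterministic_bitwise(self):
        model = PixelBNN(TINY, seed=0)
        x = np.random.default_rng(1).standard_normal((2, 16, 16, 3)).astype(np.float32)
        assert np.array_equal(model.forward(x), model.forward(x))

    def test_batch_of_three_and_open_unit_interval(self):
        model = PixelBNN(TINY, seed=0)
        x = np.random.default_rng(2).standard_normal((3, 16, 16, 3)).astype(np.float32)
        out = model.forward(x)
        assert out.shape == (3, 16, 16)
        assert out.min() > 0.0 and out.max() < 1.0

    def test_training_mode_dropout_differs_from_inference(self):
        model = PixelBNN(TINY, seed=0)
        x = np.random.default_rng(3).standard_normal((1, 16, 16, 3)).astype(np.float32)
        infer = model.forward(x, training=False)
        trained = model.forward(x, training=True, rng=np.random.default_rng(0))
        assert not np.array_equal(infer, trained)


class TestSegmentationLoss:
    def test_uniform_half_prediction_gives_ln2(self):
        pred = np.full((8, 8), 0.5)
        truth = (np.random.default_rng(0).random((8, 8)) > 0.5).astype(float)
        assert segmentation_loss(pred, truth) == pytest.approx(math.log(2), rel=1e-9)

    def test_confident_correct_prediction_approaches_zero(self):
        truth = (np.random.default_rng(1).random((8, 8)) > 0.7).astype(float)
        for margin, prev in ((1e-2, None), (1e-4, 1e-2), (1e-6, 1e-4)):
            pred = np.where(truth == 1, 1.0 - margin, margin)
            loss = segmentation_loss(pred, truth)
            assert loss < 2 * margin  # -> 0 in the confident limit
        assert segmentation_loss(truth, truth) < 1e-10

    def test_random_case_matches_per_pixel_loop(self):
        rng = np.random.default_rng(4)
        pred = rng.uniform(0.05, 0.95, size=(4, 4))
        truth = (rng.random((4, 4)) > 0.5).astype(float)
        total = 0.0
        for i in range(4):
            for j in range(4):
                p, t = pred[i, j], truth[i, j]
                total += -(t * math.log(p) + (1 - t) * math.log(1 - p))
        assert segmentation_loss(pred, truth) == pytest.approx(total / 16, rel=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            segmentation_loss(np.zeros((4, 4)), np.zeros((4, 5)))


class TestTransposedConvAdjoint:
    def test_matches_conv_adjoint_inner_product(self):
        """<conv(x), y> == <x, conv_T(y)> — the defining adjoint identity."""
        rng = np.random.default_rng(0)
        w = ad.Parameter(rng.standard_normal((3, 3, 5, 7)).astype(np.float32))
        b0 = ad.Parameter(np.zeros(7, np.float32))
        x = ad.Tensor(rng.standard_normal((2, 8, 8, 5)).astype(np.float32))
        y = rng.standard_normal((2, 4, 4, 7)).astype(np.float32)
        fwd = ad.conv2d(x, w, b0, stride=2)
        lhs = float(np.sum(fwd.data * y))
        # the (k,k,Cout,Cin) transposed-conv layout of the same kernel is the
        # conv weight array itself read with its roles swapped
        wt = ad.Parameter(w.data.copy())
        bt = ad.Parameter(np.zeros(5, np.float32))
        adj = ad.conv_transpose2d(ad.Tensor(y), wt, bt, stride=2)
        rhs = float(np.sum(x.data * adj.data))
        assert lhs == pytest.approx(rhs, rel=1e-4)
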