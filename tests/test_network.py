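"""MD-Unet architecture, autograd correctness and the customized loss."""

import numpy as np
import pytest

from pcdmd import network as nw
from pcdmd.nn import tape
from pcdmd.nn.tape import Tensor


def numerical_gradient(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    for _ in it:
        i = it.multi_index
        x[i] += eps
        fp = f()
        x[i] -= 2 * eps
        fm = f()
        x[i] += eps
        g[i] = (fp - fm) / (2 * eps)
    return g


class TestAutogradOps:
    """Reverse-mode gradients match float64 central differences."""

    rng = np.random.default_rng(0)

    def _check(self, make_loss, *tensors, tol=1e-6):
        for t in tensors:
            t.zero_grad()
        make_loss().backward()
        for t in tensors:
            ng = numerical_gradient(lambda: float(make_loss().data), t.data)
            assert np.abs(t.grad - ng).max() <= tol * max(np.abs(ng).max(), 1e-8)

    def test_conv3d(self):
        x = Tensor(self.rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
        w = Tensor(self.rng.normal(size=(3, 2, 3, 3, 3)) * 0.3, requires_grad=True)
        b = Tensor(self.rng.normal(size=3) * 0.1, requires_grad=True)
        self._check(lambda: tape.power(tape.conv3d(x, w, b), 2.0).sum(), x, w, b)

    def test_conv3d_preserves_bin_depth(self):
        x = Tensor(self.rng.normal(size=(1, 3, 8, 8)))
        w = Tensor(self.rng.normal(size=(4, 1, 3, 3, 3)))
        b = Tensor(np.zeros(4))
        assert tape.conv3d(x, w, b).data.shape == (4, 3, 8, 8)

    def test_batchnorm_train(self):
        x = Tensor(self.rng.normal(size=(3, 2, 4, 4)), requires_grad=True)
        g = Tensor(self.rng.normal(size=3), requires_grad=True)
        b = Tensor(self.rng.normal(size=3), requires_grad=True)
        self._check(lambda: tape.power(tape.batchnorm(x, g, b)[0], 2.0).sum(), x, g, b, tol=1e-3)

    def test_conv_transpose(self):
        x = Tensor(self.rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        w = Tensor(self.rng.normal(size=(2, 3, 2, 2)) * 0.4, requires_grad=True)
        b = Tensor(self.rng.normal(size=3) * 0.1, requires_grad=True)
        out = tape.conv_transpose_spatial(x, w, b)
        assert out.data.shape == (3, 3, 8, 8)
        self._check(lambda: tape.power(tape.conv_transpose_spatial(x, w, b), 2.0).sum(), x, w, b)

    def test_maxpool(self):
        x = Tensor(self.rng.normal(size=(2, 3, 6, 6)), requires_grad=True)
        assert tape.maxpool_spatial(x).data.shape == (2, 3, 3, 3)
        self._check(lambda: tape.power(tape.maxpool_spatial(x), 2.0).sum(), x)

    def test_sobel_conv_with_reflect_padding(self):
        x = Tensor(self.rng.normal(size=(2, 7, 7)), requires_grad=True)
        self._check(lambda: tape.power(tape.conv2d_fixed(x, nw.SOBEL_H), 2.0).sum(), x)

    def test_softmax_and_losses(self):
        oh = nw.one_hot(self.rng.integers(0, 4, (5, 5)))
        x = Tensor(self.rng.normal(size=(4, 5, 5)), requires_grad=True)
        cfg = nw.LossConfig()
        self._check(lambda: nw.focal_loss(tape.softmax(x, 0), oh, cfg), x, tol=1e-5)
        self._check(lambda: nw.mge_loss(tape.softmax(x, 0), oh, cfg), x, tol=1e-5)

    def test_gate_and_concat(self):
        x = Tensor(self.rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        y = Tensor(self.rng.normal(size=(2, 3, 4, 4)), requires_grad=True)
        g = Tensor(np.asarray(1.3), requires_grad=True)
        self._check(
            lambda: tape.power(tape.concat(tape.scale(x, g), y, axis=0), 2.0).sum(), x, y, g
        )


class TestArchitecture:
    def test_hidden_layer_audit_and_deepest_channels(self):
        """The default network audits to 29 hidden layers and 1024 channels."""
        net = nw.build_network(nw.NetworkConfig(), seed=0)
        assert nw.count_hidden_layers(net) == 29
        assert net.config.channels(net.config.n_scales) == 1024
        deepest = net._modules["enc5.conv1"].w.data.shape[0]
        assert deepest == 1024

    def test_channel_doubling(self):
        cfg = nw.NetworkConfig()
        assert [cfg.channels(k) for k in range(1, 6)] == [64, 128, 256, 512, 1024]

    def test_layer_count_small_config_hand_count(self):
        """n_scales=2 without gates: 4 enc + 1 pool + 1 up + 2 dec + 1 head = 9."""
        cfg = nw.NetworkConfig(n_scales=2, base_channels=4, weighted_skip_scales=())
        assert nw.count_hidden_layers(nw.build_network(cfg, seed=0)) == 9

    def test_gates_add_exactly_two(self):
        with_g = nw.build_network(nw.NetworkConfig(n_scales=3, base_channels=4), seed=0)
        without = nw.build_network(
            nw.NetworkConfig(n_scales=3, base_channels=4, weighted_skip_scales=()), seed=0
        )
        assert nw.count_hidden_layers(with_g) - nw.count_hidden_layers(without) == 2

    def test_forward_simplex_output(self):
        net = nw.build_network(nw.NetworkConfig(n_scales=3, base_channels=4), seed=1)
        x = np.random.default_rng(0).random((3, 32, 32)).astype(np.float32)
        p = net.forward(x).data
        assert p.shape == (4, 32, 32)
        assert np.abs(p.sum(axis=0) - 1.0).max() < 1e-5
        assert p.min() >= 0

    def test_simplex_invariant_many_random_inputs(self):
        """Per-pixel probabilities stay on the simplex across random passes."""
        net = nw.build_network(nw.NetworkConfig(n_scales=2, base_channels=2), seed=2).eval()
        rng = np.random.default_rng(3)
        for _ in range(1000):
            p = net.forward(rng.normal(size=(3, 8, 8)).astype(np.float32)).data
            assert np.abs(p.sum(axis=0) - 1.0).max() < 1e-5 and p.min() >= 0

    def test_wrong_bin_depth_rejected(self):
        net = nw.build_network(nw.NetworkConfig(n_scales=2, base_channels=2), seed=0)
        with pytest.raises(ValueError):
            net.forward(np.zeros((2, 16, 16), dtype=np.float32))

    def test_non_divisible_input_padded_and_cropped(self):
        net = nw.build_network(nw.NetworkConfig(n_scales=3, base_channels=2), seed=0)
        p = net.forward(np.random.default_rng(0).random((3, 30, 26)).astype(np.float32)).data
        assert p.shape == (4, 30, 26)

    def test_gradient_reaches_every_parameter(self):
        net = nw.build_network(nw.NetworkConfig(n_scales=3, base_channels=2), seed=0)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(3, 16, 16)).astype(np.float32)
        oh = nw.one_hot(rng.integers(0, 4, (16, 16)))
        loss = nw.total_loss(net.forward(x), oh)
        net.zero_grad()
        loss.backward()
        for name, p in net.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), name


class TestFocalLoss:
    def test_gamma0_unit_weights_is_cross_entropy(self):
        """gamma=0, w_b=1 reduces to the mean cross-entropy (independent oracle)."""
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(4, 9, 9))
        p = np.exp(logits) / np.exp(logits).sum(axis=0, keepdims=True)
        lab = rng.integers(0, 4, (9, 9))
        oh = nw.one_hot(lab)
        ce = -np.log(np.take_along_axis(p, lab[None], axis=0)[0]).mean()
        cfg = nw.LossConfig(gamma=0.0, w_b=1.0, lam=0.0)
        assert nw.focal_loss(p, oh, cfg) == pytest.approx(ce, abs=1e-6)

    def test_perfect_prediction_is_near_zero(self):
        lab = np.random.default_rng(1).integers(0, 4, (8, 8))
        oh = nw.one_hot(lab)
        assert nw.focal_loss(oh, oh) <= 1e-12

    def test_single_pixel_hand_arithmetic(self):
        """One pixel, two classes, p=(0.9, 0.1), truth class 0, gamma=2."""
        p = np.array([[[0.9]], [[0.1]]])
        oh = np.array([[[1.0]], [[0.0]]])
        cfg = nw.LossConfig(gamma=2.0, w_b=1.0)
        assert nw.focal_loss(p, oh, cfg) == pytest.approx(-0.1**2 * np.log(0.9), rel=1e-12)

    def test_background_weight_scales_background_pixels(self):
        p = np.full((2, 1, 1), 0.5)
        oh_bg = np.array([[[1.0]], [[0.0]]])
        l_full = nw.focal_loss(p, oh_bg, nw.LossConfig(gamma=0.0, w_b=1.0))
        l_quarter = nw.focal_loss(p, oh_bg, nw.LossConfig(gamma=0.0, w_b=0.25))
        assert l_quarter == pytest.approx(0.25 * l_full, rel=1e-12)

    def test_brute_force_transcription_5x5(self):
        """Vectorized focal loss equals a literal per-pixel loop of the formula."""
        rng = np.random.default_rng(2)
        raw = rng.random((4, 5, 5)) + 0.05
        p = raw / raw.sum(axis=0)
        lab = rng.integers(0, 4, (5, 5))
        oh = nw.one_hot(lab)
        cfg = nw.LossConfig(gamma=2.0, w_b=0.25)
        acc = 0.0
        for i in range(5):
            for j in range(5):
                for cls in range(4):
                    if lab[i, j] == cls:
                        w = cfg.w_b if cls == 0 else 1.0
                        acc += -w * (1 - p[cls, i, j]) ** cfg.gamma * np.log(p[cls, i, j])
        assert nw.focal_loss(p, oh, cfg) == pytest.approx(acc / 25.0, rel=1e-12)

    def test_loss_decreases_along_mixing_path(self):
        """Focal loss strictly decreases as prediction mixes toward the truth."""
        rng = np.random.default_rng(3)
        raw = rng.random((4, 6, 6)) + 0.05
        p0 = raw / raw.sum(axis=0)
        oh = nw.one_hot(rng.integers(0, 4, (6, 6)))
        losses = [
            nw.focal_loss((1 - t) * p0 + t * oh, oh) for t in np.linspace(0.0, 0.999, 11)
        ]
        assert all(a > b for a, b in zip(losses, losses[1:]))

    def test_non_simplex_input_rejected(self):
        with pytest.raises(ValueError):
            nw.focal_loss(np.full((4, 3, 3), 0.5), nw.one_hot(np.zeros((3, 3), dtype=int)))


class TestMgeLoss:
    def test_identical_maps_zero(self):
        oh = nw.one_hot(np.random.default_rng(0).integers(0, 4, (8, 8)))
        assert nw.mge_loss(oh, oh) == 0.0

    def test_constant_maps_zero(self):
        """Sobel of spatially constant fields vanishes under reflect padding."""
        p = np.full((4, 6, 6), 0.25)
        gt = np.zeros((4, 6, 6))
        gt[2] = 1.0
        assert nw.mge_loss(p, gt) == pytest.approx(0.0, abs=1e-12)

    def test_brute_force_step_edge_5x5(self):
        """MGE of a step edge vs a flat prediction matches a loop transcription."""
        gt = np.zeros((2, 5, 5))
        gt[0, :, :2] = 1.0
        gt[1] = 1.0 - gt[0]
        p = np.full((2, 5, 5), 0.5)
        cfg = nw.LossConfig()

        def grad_sq(field):
            padded = np.pad(field, 1, mode="reflect")
            gh = np.zeros((5, 5))
            gv = np.zeros((5, 5))
            for i in range(5):
                for j in range(5):
                    for a in range(3):
                        for b in range(3):
                            gh[i, j] += padded[i + a, j + b] * cfg.sobel_h[a, b]
                            gv[i, j] += padded[i + a, j + b] * cfg.sobel_v[a, b]
            return gh**2 + gv**2

        expected = sum(((grad_sq(gt[c]) - grad_sq(p[c])) ** 2).sum() for c in range(2)) / 25.0
        assert nw.mge_loss(p, gt, cfg) == pytest.approx(expected, rel=1e-12)


class TestTotalLoss:
    def test_lambda_zero_equals_focal(self):
        rng = np.random.default_rng(4)
        raw = rng.random((4, 5, 5)) + 0.05
        p = raw / raw.sum(axis=0)
        oh = nw.one_hot(rng.integers(0, 4, (5, 5)))
        cfg = nw.LossConfig(lam=0.0)
        assert nw.total_loss(p, oh, cfg) == nw.focal_loss(p, oh, cfg)

    def test_total_is_focal_plus_lambda_mge(self):
        rng = np.random.default_rng(5)
        raw = rng.random((4, 5, 5)) + 0.05
        p = raw / raw.sum(axis=0)
        oh = nw.one_hot(rng.integers(0, 4, (5, 5)))
        cfg = nw.LossConfig()
        expected = nw.focal_loss(p, oh, cfg) + cfg.lam * nw.mge_loss(p, oh, cfg)
        assert nw.total_loss(p, oh, cfg) == pytest.approx(expected, rel=1e-12)

    def test_perfect_prediction_near_zero(self):
        oh = nw.one_hot(np.random.default_rng(6).integers(0, 4, (8, 8)))
        assert nw.total_loss(oh, oh) <= 1e-12
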