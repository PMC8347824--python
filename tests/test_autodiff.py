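"""Gradient correctness of the autodiff engine against central finite
differences, plus optimizer and determinism contracts."""

from __future__ import annotations

import numpy as np
import pytest

from otoshuffle import nn
from otoshuffle.nn import Tensor

RNG = np.random.default_rng(1234)


def _fd_check(forward, tensors: dict[str, Tensor], n_probe: int = 6, eps: float = 1e-2, tol: float = 3e-2):
    """Compare analytic gradients of a scalar ``forward()`` against central
    differences at randomly probed coordinates of every input tensor."""
    loss = forward()
    for t in tensors.values():
        t.grad = None
    loss.backward()
    for name, t in tensors.items():
        assert t.grad is not None, f"no gradient reached {name}"
        flat = t.data.reshape(-1)
        probes = RNG.choice(flat.size, size=min(n_probe, flat.size), replace=False)
        for idx in probes:
            orig = flat[idx]
            flat[idx] = orig + eps
            lp = forward().item()
            flat[idx] = orig - eps
            lm = forward().item()
            flat[idx] = orig
            num = (lp - lm) / (2 * eps)
            ana = t.grad.reshape(-1)[idx]
            assert ana == pytest.approx(num, abs=tol, rel=tol), f"{name}[{idx}]: analytic {ana} vs numeric {num}"


def _sum(t: Tensor) -> Tensor:
    # scalar reduction via repeated mean-free ops: flatten then matmul with ones
    flat = t.reshape(1, -1)
    ones = Tensor(np.ones((1, flat.shape[1]), dtype=np.float32))
    return nn.linear(flat, ones)


class TestGradients:
    def test_conv2d_strided_padded(self):
        x = Tensor(RNG.normal(size=(2, 3, 6, 6)), requires_grad=True)
        w = Tensor(0.3 * RNG.normal(size=(4, 3, 3, 3)), requires_grad=True)
        b = Tensor(RNG.normal(size=4), requires_grad=True)
        _fd_check(lambda: _sum(nn.conv2d(x, w, b, stride=2, padding=1)), {"x": x, "w": w, "b": b})

    def test_linear(self):
        x = Tensor(RNG.normal(size=(3, 5)), requires_grad=True)
        w = Tensor(0.3 * RNG.normal(size=(2, 5)), requires_grad=True)
        b = Tensor(RNG.normal(size=2), requires_grad=True)
        _fd_check(lambda: _sum(nn.linear(x, w, b)), {"x": x, "w": w, "b": b})

    def test_batchnorm_training_mode(self):
        x = Tensor(RNG.normal(size=(4, 3, 5, 5)), requires_grad=True)
        g = Tensor(1.0 + 0.1 * RNG.normal(size=3), requires_grad=True)
        be = Tensor(0.1 * RNG.normal(size=3), requires_grad=True)

        def fwd():
            rm, rv = np.zeros(3, np.float32), np.ones(3, np.float32)
            out = nn.batch_norm2d(x, g, be, rm, rv, training=True)
            return _sum(nn.mul(out, np.random.default_rng(7).normal(size=out.shape).astype(np.float32)))

        _fd_check(fwd, {"x": x, "gamma": g, "beta": be})

    def test_maxpool(self):
        # distinct values spaced wider than the FD step, so no probe sits on
        # an argmax tie (where max pooling is not differentiable)
        vals = np.random.default_rng(3).permutation(2 * 2 * 6 * 6) * 0.13
        x = Tensor(vals.reshape(2, 2, 6, 6), requires_grad=True)
        _fd_check(lambda: _sum(nn.max_pool2d(x, 3, 2, 1)), {"x": x})

    def test_shuffle_attention_path(self):
        """space_to_depth -> conv1x1 -> sigmoid -> upsample -> gate."""
        x = Tensor(RNG.normal(size=(2, 2, 4, 4)), requires_grad=True)
        w = Tensor(0.3 * RNG.normal(size=(2, 8, 1, 1)), requires_grad=True)

        def fwd():
            a = nn.upsample_nearest2x(nn.sigmoid(nn.conv2d(nn.space_to_depth(x), w)))
            return _sum(nn.mul(x, a))

        _fd_check(fwd, {"x": x, "w": w})

    def test_cbam_descriptor_ops(self):
        x = Tensor(RNG.normal(size=(2, 3, 4, 4)), requires_grad=True)

        def fwd():
            pooled = nn.concat_channels(nn.channel_mean(x), nn.channel_max(x))
            desc = nn.add(nn.spatial_mean(x), nn.spatial_max(x))
            return _sum(nn.add(_sum(pooled), _sum(desc)))

        _fd_check(fwd, {"x": x})

    def test_softmax_cross_entropy(self):
        logits = Tensor(RNG.normal(size=(5, 4)), requires_grad=True)
        labels = np.array([0, 1, 2, 3, 1])
        _fd_check(lambda: nn.softmax_cross_entropy(logits, labels), {"logits": logits}, tol=1e-2)

    def test_weighted_cross_entropy_reduces_to_mean(self):
        logits = Tensor(RNG.normal(size=(6, 4)))
        labels = np.array([0, 1, 2, 3, 1, 0])
        plain = nn.softmax_cross_entropy(logits, labels).item()
        uniform = nn.softmax_cross_entropy(logits, labels, class_weights=np.full(4, 3.0)).item()
        assert uniform == pytest.approx(plain, rel=1e-6)


class TestSpaceToDepth:
    def test_forced_phase_order(self):
        x = Tensor(np.array([[[[1.0, 2.0], [3.0, 4.0]]]]))
        out = nn.space_to_depth(x)
        assert out.shape == (1, 4, 1, 1)
        np.testing.assert_array_equal(out.data.reshape(4), [1, 2, 3, 4])

    @pytest.mark.parametrize("shape", [(1, 1, 2, 2), (2, 8, 16, 16), (3, 5, 4, 6)])
    def test_bijection_and_multiset(self, shape):
        x = Tensor(np.random.default_rng(9).normal(size=shape).astype(np.float32))
        rt = nn.depth_to_space(nn.space_to_depth(x))
        np.testing.assert_array_equal(rt.data, x.data)
        out = nn.space_to_depth(x)
        assert out.data.size == x.data.size
        np.testing.assert_array_equal(np.sort(out.data.reshape(-1)), np.sort(x.data.reshape(-1)))

    def test_odd_dims_rejected(self):
        with pytest.raises(ValueError, match="even"):
            nn.space_to_depth(Tensor(np.zeros((1, 1, 3, 4))))


class TestOptimizers:
    def _step(self, opt_cls, **kw):
        w = Tensor(np.ones((2, 2), np.float32), requires_grad=True)
        opt = opt_cls([w], **kw)
        x = Tensor(np.full((1, 2), 2.0, np.float32))
        loss = _sum(nn.linear(x, w))
        opt.zero_grad()
        loss.backward()
        opt.step()
        return w.data

    def test_zero_lr_leaves_parameters_unchanged(self):
        np.testing.assert_array_equal(self._step(nn.SGD, lr=0.0), np.ones((2, 2)))
        np.testing.assert_array_equal(self._step(nn.Adam, lr=0.0), np.ones((2, 2)))

    def test_sgd_moves_against_gradient(self):
        out = self._step(nn.SGD, lr=0.1, momentum=0.0)
        assert np.all(out < 1.0)  # gradient of sum(x @ w.T) w.r.t. w is positive


def test_state_dict_roundtrip():
    net = nn.Sequential(nn.Conv2d(3, 4, 3, padding=1, rng=np.random.default_rng(0)), nn.BatchNorm2d(4))
    state = net.state_dict()
    net2 = nn.Sequential(nn.Conv2d(3, 4, 3, padding=1, rng=np.random.default_rng(5)), nn.BatchNorm2d(4))
    net2.load_state_dict(state)
    x = Tensor(np.random.default_rng(2).normal(size=(1, 3, 4, 4)).astype(np.float32))
    net.eval(), net2.eval()
    np.testing.assert_array_equal(net(x).data, net2(x).data)
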