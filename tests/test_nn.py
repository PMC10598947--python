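"""Gradient and contract checks for the numpy network engine."""

import numpy as np
import pytest

from m3mc import nn
from m3mc.nn import Tensor


def numeric_grad(f, arr, index, eps=1e-6):
    arr[index] += eps
    up = f()
    arr[index] -= 2 * eps
    down = f()
    arr[index] += eps
    return (up - down) / (2 * eps)


class TestAutogradPrimitives:
    @pytest.mark.parametrize(
        "op",
        [
            lambda x: (x * 3.0 + 1.0).sum(),
            lambda x: (x**2).mean(),
            lambda x: (x.exp() + 1.0).log().sum(),
            lambda x: x.relu().sum(),
            lambda x: x.sigmoid().sum(),
            lambda x: (x / (x**2 + 1.0)).sum(),
            lambda x: x.reshape((6, 4)).transpose((1, 0)).sum(axis=1).sum(),
            lambda x: x[1:, :2, :].sum(),
            lambda x: x.pad([(1, 1), (0, 2), (1, 0)]).mean(),
        ],
    )
    def test_elementwise_and_shape_ops(self, op, rng):
        data = rng.normal(size=(2, 3, 4)) + 0.1
        x = Tensor(data, requires_grad=True)
        op(x).backward()
        for index in [(0, 0, 0), (1, 2, 3), (0, 1, 2)]:
            num = numeric_grad(lambda: float(op(Tensor(data)).data), data, index)
            assert x.grad[index] == pytest.approx(num, abs=1e-6)

    def test_matmul_gradients(self, rng):
        a_data = rng.normal(size=(3, 4))
        b_data = rng.normal(size=(4, 2))
        a, b = Tensor(a_data, requires_grad=True), Tensor(b_data, requires_grad=True)
        (a @ b).sum().backward()
        num_a = numeric_grad(
            lambda: float((Tensor(a_data) @ Tensor(b_data)).sum().data), a_data, (1, 2)
        )
        num_b = numeric_grad(
            lambda: float((Tensor(a_data) @ Tensor(b_data)).sum().data), b_data, (3, 1)
        )
        assert a.grad[1, 2] == pytest.approx(num_a, abs=1e-6)
        assert b.grad[3, 1] == pytest.approx(num_b, abs=1e-6)

    def test_concat_gradient_routing(self, rng):
        a_data, b_data = rng.normal(size=(2, 3)), rng.normal(size=(2, 2))
        a, b = Tensor(a_data, requires_grad=True), Tensor(b_data, requires_grad=True)
        out = nn.concat([a, b], axis=1)
        (out * out).sum().backward()
        np.testing.assert_allclose(a.grad, 2 * a_data)
        np.testing.assert_allclose(b.grad, 2 * b_data)

    def test_broadcast_add_sums_gradient(self, rng):
        x = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        bias = Tensor(rng.normal(size=(3,)), requires_grad=True)
        (x + bias).sum().backward()
        np.testing.assert_allclose(bias.grad, np.full(3, 4.0))


class TestLayers:
    @pytest.mark.parametrize("ndim,shape", [(2, (2, 2, 6, 6)), (3, (1, 2, 4, 4, 4))])
    def test_conv_gradcheck(self, ndim, shape, rng):
        conv = nn.Conv(2, 3, 3, ndim=ndim, rng=rng)
        data = rng.normal(size=shape)

        def loss():
            return float((conv(Tensor(data)) ** 2).sum().data)

        x = Tensor(data, requires_grad=True)
        (conv(x) ** 2).sum().backward()
        index = (0, 1) + (2,) * ndim
        assert x.grad[index] == pytest.approx(numeric_grad(loss, data, index), rel=1e-5)
        w = conv.weight.data
        widx = (1, 0) + (1,) * ndim
        assert conv.weight.grad[widx] == pytest.approx(
            numeric_grad(loss, w, widx), rel=1e-5
        )

    def test_conv_same_padding_shape(self, rng):
        conv = nn.Conv(1, 4, 3, ndim=2, rng=rng)
        out = conv(Tensor(rng.normal(size=(2, 1, 8, 10))))
        assert out.shape == (2, 4, 8, 10)

    def test_maxpool_forward_and_grad(self, rng):
        data = rng.normal(size=(1, 1, 4, 4))
        x = Tensor(data, requires_grad=True)
        pooled, _ = nn.max_pool(x, (2, 2))
        assert pooled.shape == (1, 1, 2, 2)
        assert pooled.data[0, 0, 0, 0] == data[0, 0, :2, :2].max()
        pooled.sum().backward()
        # gradient routed only to the argmax of each window
        assert x.grad.sum() == 4
        assert x.grad.max() == 1

    def test_unpool_inverts_pool_support(self, rng):
        data = rng.normal(size=(1, 2, 4, 4))
        x = Tensor(data, requires_grad=True)
        pooled, state = nn.max_pool(x, (2, 2))
        restored = nn.max_unpool(pooled, state)
        assert restored.shape == x.shape
        # restored keeps exactly the window maxima in place
        np.testing.assert_allclose(restored.data.max(axis=(2, 3)), pooled.data.max(axis=(2, 3)))
        restored.sum().backward()

    def test_upsample_then_sum_grad(self, rng):
        data = rng.normal(size=(1, 1, 2, 3))
        x = Tensor(data, requires_grad=True)
        up = nn.upsample_nearest(x, (2, 2))
        assert up.shape == (1, 1, 4, 6)
        up.sum().backward()
        np.testing.assert_allclose(x.grad, np.full((1, 1, 2, 3), 4.0))

    def test_batchnorm_normalizes_and_gradchecks(self, rng):
        bn = nn.BatchNorm(3)
        data = rng.normal(2.0, 4.0, size=(8, 3, 5))
        out = bn(Tensor(data))
        assert np.allclose(out.data.mean(axis=(0, 2)), 0, atol=1e-7)
        assert np.allclose(out.data.std(axis=(0, 2)), 1, atol=1e-3)

        def loss():
            bn2 = nn.BatchNorm(3)
            return float((bn2(Tensor(data)) ** 2).sum().data)

        x = Tensor(data, requires_grad=True)
        (nn.BatchNorm(3)(x) ** 2).sum().backward()
        idx = (3, 1, 2)
        assert x.grad[idx] == pytest.approx(numeric_grad(loss, data, idx), abs=1e-4)

    def test_batchnorm_eval_uses_running_stats(self, rng):
        bn = nn.BatchNorm(2)
        for _ in range(200):
            bn(Tensor(rng.normal(5.0, 2.0, size=(16, 2, 4))))
        bn.set_training(False)
        out = bn(Tensor(np.full((1, 2, 4), 5.0)))
        assert np.allclose(out.data, 0, atol=0.2)

    def test_softmax_is_distribution(self, rng):
        p = nn.softmax(Tensor(rng.normal(size=(5, 4)) * 10))
        np.testing.assert_allclose(p.data.sum(axis=1), 1, atol=1e-12)

    def test_adam_minimizes_quadratic(self):
        x = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = nn.Adam([x], lr=0.2)
        for _ in range(150):
            loss = (x**2).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(x.data).max() < 1e-2


class TestSchedules:
    def test_plateau_halves_after_patience(self):
        x = Tensor(np.zeros(1), requires_grad=True)
        opt = nn.Adam([x], lr=1.0)
        sched = nn.ReduceLROnPlateau(opt, factor=0.5, patience=3)
        sched.step(1.0)
        for _ in range(3):
            assert not opt.lr < 1.0
            sched.step(1.0)
        sched.step(1.0)
        assert opt.lr == 0.5

    def test_plateau_resets_on_improvement(self):
        x = Tensor(np.zeros(1), requires_grad=True)
        opt = nn.Adam([x], lr=1.0)
        sched = nn.ReduceLROnPlateau(opt, factor=0.5, patience=2)
        for loss in [1.0, 1.0, 0.5, 0.5, 0.5]:
            sched.step(loss)
        assert opt.lr == 1.0

    def test_step_decay_fixed_schedule(self):
        x = Tensor(np.zeros(1), requires_grad=True)
        opt = nn.Adam([x], lr=1.0)
        sched = nn.StepDecay(opt, factor=0.5, every=2)
        for _ in range(4):
            sched.step()
        assert opt.lr == 0.25
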