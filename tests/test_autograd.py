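"""Gradient checks for the tensor engine against central differences."""

import numpy as np
import pytest

from gaitxai.nn.autograd import (Tensor, concat, conv1d,
                                 softmax_cross_entropy)


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x, dtype=np.float64)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        xp = x.copy(); xp[i] += eps
        xm = x.copy(); xm[i] -= eps
        g[i] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g


def check(build, x, rtol=1e-5, atol=1e-7):
    xt = Tensor(x.copy(), requires_grad=True)
    out = build(xt)
    out.sum().backward() if out.data.ndim else out.backward()
    num = numeric_grad(lambda v: float(build(Tensor(v)).data.sum()), x)
    np.testing.assert_allclose(xt.grad, num, rtol=rtol, atol=atol)


RNG = np.random.default_rng(0)


@pytest.mark.parametrize("op", [
    lambda t: t.relu(), lambda t: t.tanh(), lambda t: t.sigmoid(),
    lambda t: t.exp(), lambda t: (t * t + 1.0).log(),
    lambda t: (t * t + 0.5).sqrt(), lambda t: t * 3.0 - 1.0,
    lambda t: t ** 3,
])
def test_elementwise_grads(op):
    check(op, RNG.normal(size=(4, 5)))


@pytest.mark.parametrize("axis,keepdims", [(None, False), (0, False),
                                           (1, True)])
def test_reductions(axis, keepdims):
    check(lambda t: t.sum(axis=axis, keepdims=keepdims),
          RNG.normal(size=(3, 4)))
    check(lambda t: t.mean(axis=axis, keepdims=keepdims),
          RNG.normal(size=(3, 4)))


def test_max_reduction_grad():
    x = RNG.normal(size=(3, 4))
    check(lambda t: t.max(axis=1), x)


def test_matmul_grad_both_sides():
    a = RNG.normal(size=(3, 4))
    b = RNG.normal(size=(4, 2))
    at = Tensor(a.copy(), requires_grad=True)
    bt = Tensor(b.copy(), requires_grad=True)
    (at @ bt).sum().backward()
    np.testing.assert_allclose(
        at.grad, numeric_grad(lambda v: float((v @ b).sum()), a), rtol=1e-6)
    np.testing.assert_allclose(
        bt.grad, numeric_grad(lambda v: float((a @ v).sum()), b), rtol=1e-6)


def test_broadcast_add_unbroadcasts_grad():
    a = Tensor(RNG.normal(size=(3, 4)), requires_grad=True)
    b = Tensor(RNG.normal(size=(4,)), requires_grad=True)
    (a + b).sum().backward()
    assert b.grad.shape == (4,)
    np.testing.assert_allclose(b.grad, np.full(4, 3.0))


def test_getitem_scatter_grad():
    x = RNG.normal(size=(2, 6, 3))
    check(lambda t: t[:, ::2, :], x)


@pytest.mark.parametrize("stride,dilation,padding", [
    (1, 1, (0, 0)), (2, 1, (2, 2)), (1, 2, (2, 1)), (3, 1, (1, 1)),
])
def test_conv1d_grads(stride, dilation, padding):
    x = RNG.normal(size=(2, 10, 3))
    w = RNG.normal(size=(3, 3, 4))
    b = RNG.normal(size=(4,))

    def fx(v):
        return float(conv1d(Tensor(v), Tensor(w), Tensor(b), stride,
                            dilation, padding).data.sum())

    xt, wt, bt = (Tensor(x.copy(), requires_grad=True),
                  Tensor(w.copy(), requires_grad=True),
                  Tensor(b.copy(), requires_grad=True))
    conv1d(xt, wt, bt, stride, dilation, padding).sum().backward()
    np.testing.assert_allclose(xt.grad, numeric_grad(fx, x), rtol=1e-5,
                               atol=1e-7)
    fw = lambda v: float(conv1d(Tensor(x), Tensor(v), Tensor(b), stride,
                                dilation, padding).data.sum())
    np.testing.assert_allclose(wt.grad, numeric_grad(fw, w), rtol=1e-5,
                               atol=1e-7)


def test_concat_grad():
    a = RNG.normal(size=(2, 3))
    b = RNG.normal(size=(2, 2))
    at = Tensor(a.copy(), requires_grad=True)
    bt = Tensor(b.copy(), requires_grad=True)
    out = concat([at, bt], axis=1)
    upstream = RNG.normal(size=(2, 5))
    out.backward(upstream)
    np.testing.assert_allclose(at.grad, upstream[:, :3])
    np.testing.assert_allclose(bt.grad, upstream[:, 3:])


def test_softmax_cross_entropy_grad_and_value():
    logits = RNG.normal(size=(5, 4))
    onehot = np.eye(4)[RNG.integers(0, 4, 5)]
    lt = Tensor(logits.copy(), requires_grad=True)
    loss = softmax_cross_entropy(lt, onehot)
    loss.backward()
    # value against the explicit log-sum-exp form
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    np.testing.assert_allclose(float(loss.data),
                               -(onehot * logp).sum() / 5, rtol=1e-10)
    num = numeric_grad(lambda v: float(
        softmax_cross_entropy(Tensor(v), onehot).data), logits)
    np.testing.assert_allclose(lt.grad, num, rtol=1e-5, atol=1e-8)


def test_matmul_rejects_vectors():
    with pytest.raises(ValueError):
        _ = Tensor(np.ones(3)) @ Tensor(np.ones((3, 2)))
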