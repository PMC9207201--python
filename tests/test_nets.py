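"""Unit tests for the grid CNN, fusion MLP and SGD trainer."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from affectloop import nets
from affectloop.autodiff import (
    Tensor, add, grad, matmul, mul, relu, tmean, tsum,
)


# ---------------------------------------------------------------- autodiff


def test_grad_matches_finite_differences_on_composite():
    rng = np.random.default_rng(0)
    w = Tensor(rng.standard_normal((3, 2)), requires_grad=True)
    x = np.random.default_rng(1).standard_normal((5, 3))
    y = np.random.default_rng(2).standard_normal((5, 2))

    def loss_of(wdata):
        h = np.maximum(x @ wdata, 0.0)
        return ((h - y) ** 2).mean()

    pred = relu(matmul(Tensor(x), w))
    loss = nets.mse_loss(pred, y)
    (g,) = grad(loss, [w])
    eps = 1e-6
    for i in range(3):
        for j in range(2):
            wp = w.data.copy(); wp[i, j] += eps
            wm = w.data.copy(); wm[i, j] -= eps
            fd = (loss_of(wp) - loss_of(wm)) / (2 * eps)
            assert g.data[i, j] == pytest.approx(fd, rel=1e-5, abs=1e-8)


def test_double_backward_quadratic():
    # f(w) = sum(w^2); d2f/dw2 = 2 -> grad of grad.w = 2*w then hvp = 2*v
    w = Tensor(np.array([1.5, -2.0]), requires_grad=True)
    f = tsum(mul(w, w))
    (g,) = grad(f, [w], create_graph=True)
    v = np.array([3.0, 4.0])
    inner = tsum(mul(g, Tensor(v)))
    (hv,) = grad(inner, [w])
    np.testing.assert_allclose(hv.data, 2 * v)


# -------------------------------------------------------------------- CNN


def test_cnn_forward_output_shape_and_determinism(small_tasks):
    params = nets.cnn_init(0)
    X = small_tasks[0].windows()[0][:6]
    out1 = nets.cnn_forward(params.tensors, params.running, Tensor(X), False).data
    out2 = nets.cnn_forward(params.tensors, params.running, Tensor(X), False).data
    assert out1.shape == (6, 2)
    np.testing.assert_array_equal(out1, out2)


def test_cnn_forward_zero_grid_zero_weights():
    params = nets.cnn_init(0)
    for t in params.tensors:
        t.data[...] = 0.0
    X = np.zeros((1, 6, 6, 5))
    out = nets.cnn_forward(params.tensors, params.running, Tensor(X), False).data
    np.testing.assert_array_equal(out, np.zeros((1, 2)))


def test_conv2d_hand_oracle():
    """2x2 convolution on a 2x2 single-channel input = plain dot product."""
    x = Tensor(np.arange(4.0).reshape(1, 2, 2, 1))
    w = Tensor(np.arange(4.0).reshape(2 * 2 * 1, 1) + 1.0)  # kernel flattened
    b = Tensor(np.array([0.5]))
    out = nets.conv2d(x, w, b).data
    # single output position: sum over the 2x2 patch
    expected = 0 * 1 + 1 * 2 + 2 * 3 + 3 * 4 + 0.5
    assert out.shape == (1, 1, 1, 1)
    assert out[0, 0, 0, 0] == pytest.approx(expected)


def test_cnn_shape_mismatch_errors():
    params = nets.cnn_init(0)
    with pytest.raises(Exception):
        nets.cnn_forward(
            params.tensors, params.running, Tensor(np.zeros((1, 5, 5, 5))), False
        )


# ------------------------------------------------------------------ fusion


def test_fusion_init_is_identity_on_cnn_predictions():
    params = nets.fusion_init(0)
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 1, size=(50, 4))
    out = nets.fusion_forward(params.tensors, Tensor(x), False).data
    np.testing.assert_allclose(out, x[:, :2], atol=1e-12)


def test_fusion_forward_hand_oracle():
    params = nets.fusion_init(0)
    w1 = np.zeros((4, 8)); w1[0, 0] = 2.0; w1[1, 0] = -1.0
    w2 = np.zeros((8, 2)); w2[0, 1] = 3.0
    b1 = np.full(8, 0.25); b2 = np.array([0.1, -0.2])
    for t, d in zip(params.tensors, (w1, b1, w2, b2)):
        t.data = d.astype(float)
    x = np.array([[0.5, 0.4, 0.0, 0.0]])
    # h0 = relu(2*0.5 - 1*0.4 + 0.25) = 0.85 ; out = (0.1, 0.85*3 - 0.2)
    out = nets.fusion_forward(params.tensors, Tensor(x), False).data
    np.testing.assert_allclose(out[0], [0.1, 0.85 * 3 - 0.2])


def test_fusion_inference_deterministic_dropout_only_in_training():
    params = nets.fusion_init(0)
    x = np.random.default_rng(0).uniform(0, 1, (20, 4))
    a = nets.fusion_forward(params.tensors, Tensor(x), False).data
    b = nets.fusion_forward(params.tensors, Tensor(x), False).data
    np.testing.assert_array_equal(a, b)
    rng = np.random.default_rng(1)
    tr1 = nets.fusion_forward(params.tensors, Tensor(x), True, rng=rng).data
    tr2 = nets.fusion_forward(params.tensors, Tensor(x), True, rng=rng).data
    assert not np.array_equal(tr1, tr2)  # dropout masks differ


def test_fusion_init_hidden_guard():
    with pytest.raises(ValueError, match="hidden"):
        nets.fusion_init(0, hidden=4)


# --------------------------------------------------------------- training


def _linreg_forward(tensors, x, training):
    return matmul(x, tensors[0])


def test_train_sgd_lr_zero_keeps_params():
    w0 = np.array([[1.0], [2.0]])
    tensors = [Tensor(w0.copy(), requires_grad=True)]
    X = np.random.default_rng(0).standard_normal((10, 2))
    y = X @ np.array([[3.0], [-1.0]])
    out, trace = nets.train_sgd(_linreg_forward, tensors, X, y, lr=0.0, n_iter=5)
    np.testing.assert_array_equal(out[0].data, w0)
    assert len(set(np.round(trace, 12))) == 1  # constant loss trace


def test_train_sgd_solves_linear_regression():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((100, 2))
    true_w = np.array([[0.7], [-0.3]])
    y = X @ true_w
    tensors = [Tensor(np.zeros((2, 1)), requires_grad=True)]
    out, trace = nets.train_sgd(_linreg_forward, tensors, X, y, lr=0.2, n_iter=200)
    np.testing.assert_allclose(out[0].data, true_w, atol=1e-3)
    assert trace[-1] < trace[0]


def test_train_sgd_empty_data_errors():
    with pytest.raises(ValueError, match="empty"):
        nets.train_sgd(_linreg_forward, [Tensor(np.zeros((2, 1)), requires_grad=True)],
                       np.zeros((0, 2)), np.zeros((0, 1)), lr=0.1, n_iter=1)


def test_train_sgd_early_stopping_returns_best():
    rng = np.random.default_rng(0)
    X = rng.standard_normal((50, 2))
    y = X @ np.array([[1.0], [1.0]])
    Xv, yv = X[:20], y[:20]
    tensors = [Tensor(np.zeros((2, 1)), requires_grad=True)]
    # diverging lr: validation should stop it and return an early iterate
    out, trace = nets.train_sgd(
        _linreg_forward, tensors, X, y, lr=1.5, n_iter=100,
        val=(Xv, yv), patience=5, max_iter=100,
    )
    best_loss = ((Xv @ out[0].data - yv) ** 2).mean()
    assert np.isfinite(best_loss)
    assert len(trace) < 100  # stopped early


def test_train_sgd_nonfinite_loss_errors():
    tensors = [Tensor(np.array([[1e200]]), requires_grad=True)]
    X = np.full((4, 1), 1e200)
    y = np.zeros((4, 1))
    with np.errstate(over="ignore"), pytest.raises(FloatingPointError):
        nets.train_sgd(_linreg_forward, tensors, X, y, lr=0.1, n_iter=3)


# ------------------------------------------------------- sklearn wrappers


def test_regressor_estimators_fit_predict(small_tasks):
    X, y = small_tasks[0].windows()
    reg = nets.CnnRegressor(n_iter=2)
    pred = reg.fit(X[:40], y[:40]).predict(X[:8])
    assert pred.shape == (8, 2)
    Xf = np.random.default_rng(0).uniform(0, 1, (60, 4))
    yf = Xf[:, :2]
    fus = nets.FusionRegressor(n_iter=5)
    pf = fus.fit(Xf, yf).predict(Xf[:7])
    assert pf.shape == (7, 2)
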