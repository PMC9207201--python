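"""Unit tests for meta-learning, fine-tuning and evaluation."""

import numpy as np
import pytest

import affectloop as al
from affectloop import metalearn as ml, nets
from affectloop.autodiff import Tensor, grad, matmul


def _linear_forward(tensors, x, training):
    return matmul(x, tensors[0])


def _toy_tasks(n_tasks=3, n=12, d=4, seed=0):
    rng = np.random.default_rng(seed)
    tasks = []
    for _ in range(n_tasks):
        w = rng.standard_normal((d, 2))
        Xs = rng.standard_normal((n, d)); ys = Xs @ w
        Xq = rng.standard_normal((n, d)); yq = Xq @ w
        tasks.append((Xs, ys, Xq, yq))
    return tasks


def _meta_loss_numpy(wdata, tasks, alpha):
    """Independent numpy oracle of the summed post-adaptation query loss."""
    total = 0.0
    for Xs, ys, Xq, yq in tasks:
        g = 2.0 * Xs.T @ (Xs @ wdata - ys) / ys.size
        wa = wdata - alpha * g
        total += ((Xq @ wa - yq) ** 2).mean()
    return total


def test_meta_gradient_matches_finite_differences():
    """Acceptance-grade check at unit scale: exact second-order gradient
    vs central finite differences on an 8-parameter linear model."""
    tasks = _toy_tasks()
    w = Tensor(np.random.default_rng(1).standard_normal((4, 2)), requires_grad=True)
    grads, _ = ml.meta_gradient(_linear_forward, [w], tasks, inner_lr=0.05)
    eps = 1e-6
    for i in range(4):
        for j in range(2):
            wp = w.data.copy(); wp[i, j] += eps
            wm = w.data.copy(); wm[i, j] -= eps
            fd = (_meta_loss_numpy(wp, tasks, 0.05)
                  - _meta_loss_numpy(wm, tasks, 0.05)) / (2 * eps)
            rel = abs(grads[0][i, j] - fd) / max(abs(fd), 1e-12)
            assert rel < 1e-4


def test_meta_gradient_alpha_zero_is_pooled_query_descent():
    tasks = _toy_tasks()
    w = Tensor(np.random.default_rng(2).standard_normal((4, 2)), requires_grad=True)
    grads, _ = ml.meta_gradient(_linear_forward, [w], tasks, inner_lr=0.0)
    pooled = np.zeros_like(w.data)
    for _, _, Xq, yq in tasks:
        g = grad(nets.mse_loss(_linear_forward([w], Tensor(Xq), True), yq), [w])
        pooled += g[0].data
    np.testing.assert_allclose(grads[0], pooled, rtol=1e-10)


def test_first_order_drops_curvature_term():
    tasks = _toy_tasks()
    w = Tensor(np.random.default_rng(3).standard_normal((4, 2)), requires_grad=True)
    g2, _ = ml.meta_gradient(_linear_forward, [w], tasks, 0.05, second_order=True)
    g1, _ = ml.meta_gradient(_linear_forward, [w], tasks, 0.05, second_order=False)
    assert not np.allclose(g2[0], g1[0])


# ------------------------------------------------------------ featurizing


def test_featurize_task(small_cohort, small_tasks):
    ft = small_tasks[0]
    assert ft.X.shape == (25, 20, 6, 6, 5)
    assert ft.y.shape == (25, 2)
    assert ft.n_pieces == 25
    Xw, yw = ft.windows([0, 3])
    assert Xw.shape == (40, 6, 6, 5)
    np.testing.assert_array_equal(yw[:20], np.tile(ft.y[0], (20, 1)))


def test_piece_indices_errors(small_tasks):
    with pytest.raises(ValueError, match="not among"):
        small_tasks[0].piece_indices([al.EmotionPoint(0.111, 0.222)])


# ------------------------------------------------------------ pretraining


def test_maml_pretrain_validates_pool_sizes(small_tasks):
    with pytest.raises(ValueError, match="at least two"):
        ml.maml_pretrain(small_tasks[:1], small_tasks[1:])
    cfg = ml.MamlConfig(support_size=25)
    with pytest.raises(ValueError, match="support"):
        ml.maml_pretrain(small_tasks, small_tasks, cfg)


def test_maml_pretrain_smoke(small_tasks):
    cfg = ml.MamlConfig(inner_lrs=(0.1,), max_iter=2, val_every=1, seed=0)
    params, info = ml.maml_pretrain(small_tasks, small_tasks, cfg)
    assert info["inner_lr"] == 0.1
    assert np.isfinite(info["val_loss"])
    pred = ml.cnn_window_predictor(params)(small_tasks[0].X[0])
    assert pred.shape == (20, 2)


def test_pooled_pretrain_smoke(small_tasks):
    cfg = ml.PooledConfig(lrs=(0.1,), max_iter=2, seed=0)
    params, info = ml.pooled_pretrain(small_tasks, small_tasks, cfg)
    assert info["lr"] == 0.1
    with pytest.raises(ValueError, match="empty"):
        ml.pooled_pretrain([], small_tasks, cfg)


# ------------------------------------------------------------ fine-tuning


def test_finetune_reduces_training_loss(small_tasks):
    ft = small_tasks[0]
    init = nets.cnn_init(0)
    idx = np.arange(ft.n_pieces)
    X, y = ft.windows(idx)

    def loss_of(params):
        p = ml.cnn_window_predictor(params)(X)
        return ((p - y) ** 2).mean()

    before = loss_of(init)
    after = loss_of(ml.finetune(init, ft, 13, n_iter=13))
    assert after < before


def test_train_method_dispatch(small_tasks):
    ft = small_tasks[0]
    init = nets.cnn_init(0)
    out = ml.train_method("C", ft, 5, seed=0)
    assert isinstance(out, nets.CnnParams)
    with pytest.raises(ValueError):
        ml.train_method("D", ft, 5)
    with pytest.raises(ValueError):
        ml.train_method("A", ft, 5)  # missing maml_init


def test_finetune_iteration_constants():
    assert ml.FINETUNE_ITERS == {"A": 13, "B": 10, "C": 25}
    assert ml.FUSION_ITERS == 100
    assert ml.FINETUNE_LR == ml.FUSION_LR == 0.1


# ------------------------------------------------------------- evaluation


def test_evaluate_rmse_oracle(small_tasks):
    ft = small_tasks[0]
    cnn = nets.cnn_init(0)
    pieces = ft.stimuli[:4]
    got = ml.evaluate_rmse(cnn, ft, pieces)
    predict = ml.cnn_window_predictor(cnn)
    preds = np.stack([predict(ft.X[i]).mean(axis=0) for i in range(4)])
    ref = np.sqrt(((preds - ft.y[:4]) ** 2).mean(axis=0))
    np.testing.assert_allclose(got, ref)
    with pytest.raises(ValueError, match="empty test set"):
        ml.evaluate_rmse(cnn, ft, [])


def test_generator_input_rmse(small_tasks):
    ft = small_tasks[0]
    rv, ra = ml.generator_input_rmse(ft, ft.stimuli[:6])
    gen = np.stack([s.as_array() for s in ft.stimuli[:6]])
    ref = np.sqrt(((gen - ft.y[:6]) ** 2).mean(axis=0))
    assert (rv, ra) == pytest.approx(tuple(ref))


def test_fusion_training_starts_at_cnn(small_tasks):
    """With the pass-through init, the untrained fusion network equals the
    clipped CNN prediction exactly."""
    ft = small_tasks[0]
    cnn = nets.cnn_init(0)
    fus0 = nets.fusion_init(0)
    predict = ml.fusion_window_predictor(cnn, fus0)
    X = ft.X[0]
    gen = np.tile(ft.stimuli[0].as_array(), (X.shape[0], 1))
    via_fusion = predict(X, gen)
    direct = np.clip(ml.cnn_window_predictor(cnn)(X), 0, 1)
    np.testing.assert_allclose(via_fusion, direct, atol=1e-12)
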