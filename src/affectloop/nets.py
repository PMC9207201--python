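"""Emotion-prediction networks.

Two predictors map onto the valence/arousal plane:

* a small convolutional network over the 6x6x5 scalp feature grid
  (three 2x2 conv blocks of 8 channels with batch normalisation and a
  rectifier, then a fully connected layer to the 2 outputs), and
* a fusion network that combines the CNN's predicted (valence, arousal)
  with the music generator's input coordinates through a 4->8->2 MLP
  with ReLU and dropout (rate 0.2) on the hidden layer.

Forward passes are *functional*: parameters are passed in explicitly as
a list of tensors, which is what lets the meta-learning outer loop
differentiate through an inner SGD step.  The sklearn-style estimators
at the bottom wrap the functional core for ordinary fit/predict use.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .autodiff import (
    Tensor, add, grad, matmul, mul, no_grad, pow_const, relu, reshape, sub,
    take_columns, tmean,
)

GRID_SHAPE = (6, 6, 5)
N_CONV_BLOCKS = 3
CONV_CHANNELS = 8
KERNEL = 2
BN_EPS = 1e-5
BN_MOMENTUM = 0.1


def _im2col_columns(h: int, w: int, c: int, k: int) -> np.ndarray:
    """Flat (spatial, channel) gather columns for a valid k x k convolution
    on NHWC input flattened to (n, h*w*c)."""
    cols = []
    for i in range(h - k + 1):
        for j in range(w - k + 1):
            for di in range(k):
                for dj in range(k):
                    base = ((i + di) * w + (j + dj)) * c
                    cols.extend(range(base, base + c))
    return np.asarray(cols, dtype=np.intp)


_IDX_CACHE: dict[tuple[int, int, int, int], np.ndarray] = {}


def _cols(h, w, c, k):
    key = (h, w, c, k)
    if key not in _IDX_CACHE:
        _IDX_CACHE[key] = _im2col_columns(h, w, c, k)
    return _IDX_CACHE[key]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor, k: int = KERNEL) -> Tensor:
    """Valid 2-D convolution on NHWC input via im2col.

    weight has shape (k*k*c_in, c_out), flattened in (di, dj, c) order.
    """
    n, h, w, c = x.shape
    ho, wo = h - k + 1, w - k + 1
    xf = reshape(x, (n, h * w * c))
    patches = take_columns(xf, _cols(h, w, c, k))          # (n, P*k*k*c)
    flat = reshape(patches, (n * ho * wo, k * k * c))
    out = add(matmul(flat, weight), bias)
    return reshape(out, (n, ho, wo, weight.shape[1]))


def batchnorm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running: tuple[np.ndarray, np.ndarray],
    training: bool,
    update_stats: bool = False,
    momentum: float = BN_MOMENTUM,
) -> Tensor:
    """Batch normalisation over all but the channel (last) axis.

    In training mode the batch statistics are used (and optionally folded
    into the running averages); in inference mode the running averages
    are used, so single-sample prediction is well defined.
    """
    axes = tuple(range(x.ndim - 1))
    bshape = (1,) * (x.ndim - 1) + (x.shape[-1],)
    g = reshape(gamma, bshape)
    b = reshape(beta, bshape)
    if training:
        mu = tmean(x, axis=axes, keepdims=True)
        xc = sub(x, mu)
        var = tmean(mul(xc, xc), axis=axes, keepdims=True)
        if update_stats:
            rm, rv = running
            rm *= 1.0 - momentum
            rm += momentum * mu.data.reshape(-1)
            rv *= 1.0 - momentum
            rv += momentum * var.data.reshape(-1)
        inv = pow_const(add(var, Tensor(BN_EPS)), -0.5)
        xhat = mul(xc, inv)
    else:
        rm, rv = running
        xhat = mul(
            sub(x, Tensor(rm.reshape(bshape))),
            Tensor(1.0 / np.sqrt(rv.reshape(bshape) + BN_EPS)),
        )
    return add(mul(xhat, g), b)


# ---------------------------------------------------------------------
# parameter containers


@dataclass
class CnnParams:
    """Trainable tensors plus batch-norm running buffers for the grid CNN.

    Tensor order: per conv block (weight, bias, gamma, beta) x3, then the
    fully connected (weight, bias).
    """

    tensors: list = field(default_factory=list)
    running: list = field(default_factory=list)   # [(mean, var)] per BN
    seed: int | None = None

    def copy(self) -> "CnnParams":
        return CnnParams(
            tensors=[Tensor(t.data.copy(), requires_grad=True) for t in self.tensors],
            running=[(m.copy(), v.copy()) for m, v in self.running],
            seed=self.seed,
        )

    def n_parameters(self) -> int:
        return int(sum(t.data.size for t in self.tensors))


@dataclass
class FusionParams:
    """Trainable tensors for the fusion MLP: (W1, b1, W2, b2)."""

    tensors: list = field(default_factory=list)
    dropout_rate: float = 0.2
    seed: int | None = None

    def copy(self) -> "FusionParams":
        return FusionParams(
            tensors=[Tensor(t.data.copy(), requires_grad=True) for t in self.tensors],
            dropout_rate=self.dropout_rate,
            seed=self.seed,
        )


def cnn_init(seed: int = 0, grid_shape=GRID_SHAPE, channels: int = CONV_CHANNELS) -> CnnParams:
    """Fan-in-scaled random initialisation of the grid CNN."""
    rng = np.random.default_rng(seed)
    h, w, c_in = grid_shape
    tensors = []
    running = []
    c_prev = c_in
    side = h
    for _ in range(N_CONV_BLOCKS):
        fan_in = KERNEL * KERNEL * c_prev
        wt = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_in, channels))
        tensors += [
            Tensor(wt, requires_grad=True),
            Tensor(np.zeros(channels), requires_grad=True),
            Tensor(np.ones(channels), requires_grad=True),   # gamma
            Tensor(np.zeros(channels), requires_grad=True),  # beta
        ]
        running.append((np.zeros(channels), np.ones(channels)))
        c_prev = channels
        side -= KERNEL - 1
    fc_in = side * side * channels
    tensors += [
        Tensor(rng.normal(0.0, 1.0 / np.sqrt(fc_in), size=(fc_in, 2)), requires_grad=True),
        Tensor(np.zeros(2), requires_grad=True),
    ]
    return CnnParams(tensors=tensors, running=running, seed=seed)


def cnn_forward(
    tensors: list,
    running: list,
    x: Tensor,
    training: bool = False,
    update_stats: bool = False,
    bn_momentum: float = BN_MOMENTUM,
) -> Tensor:
    """Grid CNN forward pass: x (n, 6, 6, 5) -> predictions (n, 2)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    if x.shape[1:] != GRID_SHAPE:
        raise ValueError(f"expected input of shape (n, {GRID_SHAPE}), got {x.shape}")
    h = x
    for blk in range(N_CONV_BLOCKS):
        w, b, gamma, beta = tensors[4 * blk: 4 * blk + 4]
        h = conv2d(h, w, b)
        h = batchnorm(h, gamma, beta, running[blk], training, update_stats,
                      momentum=bn_momentum)
        h = relu(h)
    n = h.shape[0]
    flat = reshape(h, (n, h.shape[1] * h.shape[2] * h.shape[3]))
    return add(matmul(flat, tensors[-2]), tensors[-1])


def refresh_bn_stats(params: CnnParams, X) -> None:
    """Set the batch-norm running statistics to the statistics of X.

    Called after fixed-iteration fine-tuning so that single-window
    inference normalises with the same statistics the training batch saw.
    """
    with no_grad():
        cnn_forward(
            params.tensors, params.running, Tensor(np.asarray(X, np.float64)),
            training=True, update_stats=True, bn_momentum=1.0,
        )


def fusion_init(seed: int = 0, hidden: int = 8, dropout_rate: float = 0.2) -> FusionParams:
    """Pass-through initialisation of the fusion MLP.

    All four inputs (clipped CNN prediction, generator input) live in
    [0, 1], so a ReLU unit transmits them unchanged.  Each input is
    routed through *two* hidden units (units i and i+4), and the CNN
    prediction reaches the output with weight 1/2 from each copy: at
    initialisation the fusion network *is* the CNN predictor, training
    can only blend in the generator inputs from there, and the
    two-fold redundancy halves the variance injected by dropout on the
    routing units.
    """
    if hidden < 8:
        raise ValueError("pass-through initialisation needs >= 8 hidden units")
    rng = np.random.default_rng(seed)
    w1 = rng.normal(0.0, 0.01, size=(4, hidden))
    w2 = rng.normal(0.0, 0.01, size=(hidden, 2))
    for i in range(4):          # units i and i+4 pass through input i
        w1[:, i] = 0.0
        w1[:, i + 4] = 0.0
        w1[i, i] = 1.0
        w1[i, i + 4] = 1.0
    w2[0:8, :] = 0.0
    w2[0, 0] = w2[4, 0] = 0.5   # cnn valence -> valence
    w2[1, 1] = w2[5, 1] = 0.5   # cnn arousal -> arousal
    tensors = [
        Tensor(w1, requires_grad=True),
        Tensor(np.zeros(hidden), requires_grad=True),
        Tensor(w2, requires_grad=True),
        Tensor(np.zeros(2), requires_grad=True),
    ]
    return FusionParams(tensors=tensors, dropout_rate=dropout_rate, seed=seed)


def fusion_forward(
    tensors: list,
    x: Tensor,
    training: bool = False,
    dropout_rate: float = 0.2,
    rng: np.random.Generator | None = None,
) -> Tensor:
    """Fusion MLP forward: x (n, 4) = [cnn_val, cnn_aro, gen_val, gen_aro]."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    w1, b1, w2, b2 = tensors
    h = relu(add(matmul(x, w1), b1))
    if training and dropout_rate > 0.0:
        if rng is None:
            rng = np.random.default_rng()
        keep = (rng.random(h.shape) >= dropout_rate) / (1.0 - dropout_rate)
        h = mul(h, Tensor(keep))
    return add(matmul(h, w2), b2)


def mse_loss(pred: Tensor, target) -> Tensor:
    """Mean squared error over both output coordinates."""
    t = target if isinstance(target, Tensor) else Tensor(target)
    d = sub(pred, t)
    return tmean(mul(d, d))


# ---------------------------------------------------------------------
# SGD training


def train_sgd(
    forward,
    tensors: list,
    X: np.ndarray,
    y: np.ndarray,
    lr: float,
    n_iter: int,
    batch_size: int | None = None,
    val=None,
    patience: int = 5,
    seed: int = 0,
    max_iter: int | None = None,
):
    """Plain SGD on the mean-squared-error loss.

    ``forward(tensors, Xbatch, training=True)`` must return predictions.
    One *iteration* is one full pass over the training data (a single
    full-batch step when ``batch_size`` is None, otherwise one epoch of
    shuffled mini-batches).

    If ``val = (Xv, yv)`` is given, training runs until the validation
    loss has not improved for ``patience`` consecutive iterations (or
    ``max_iter`` is reached) and the best-validation parameters are
    returned; otherwise exactly ``n_iter`` iterations are run.

    Returns ``(tensors, trace)`` where trace is the list of per-iteration
    training losses.
    """
    if len(X) == 0:
        raise ValueError("empty training data")
    rng = np.random.default_rng(seed)
    trace = []
    tensors = [Tensor(t.data.copy(), requires_grad=True) for t in tensors]

    def step(xb, yb):
        pred = forward(tensors, Tensor(xb), training=True)
        loss = mse_loss(pred, yb)
        if not np.isfinite(loss.data):
            raise FloatingPointError(
                f"non-finite training loss at iteration {len(trace)}"
            )
        gs = grad(loss, tensors)
        for t, g in zip(tensors, gs):
            t.data -= lr * g.data
        return float(loss.data)

    def val_loss():
        xv, yv = val
        pred = forward(tensors, Tensor(xv), training=False)
        return float(mse_loss(pred, yv).data)

    if val is None:
        for _ in range(n_iter):
            if batch_size is None or batch_size >= len(X):
                trace.append(step(X, y))
            else:
                order = rng.permutation(len(X))
                losses = [
                    step(X[order[i: i + batch_size]], y[order[i: i + batch_size]])
                    for i in range(0, len(X), batch_size)
                ]
                trace.append(float(np.mean(losses)))
        return tensors, trace

    best = (np.inf, [t.data.copy() for t in tensors])
    since_best = 0
    it = 0
    cap = max_iter if max_iter is not None else n_iter
    while it < cap:
        if batch_size is None or batch_size >= len(X):
            trace.append(step(X, y))
        else:
            order = rng.permutation(len(X))
            losses = [
                step(X[order[i: i + batch_size]], y[order[i: i + batch_size]])
                for i in range(0, len(X), batch_size)
            ]
            trace.append(float(np.mean(losses)))
        vl = val_loss()
        if vl < best[0]:
            best = (vl, [t.data.copy() for t in tensors])
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
        it += 1
    for t, d in zip(tensors, best[1]):
        t.data = d
    return tensors, trace


# ---------------------------------------------------------------------
# sklearn-style estimators


class CnnRegressor(BaseEstimator, RegressorMixin):
    """Grid-CNN valence/arousal regressor.

    Parameters
    ----------
    lr : learning rate of the SGD optimizer.
    n_iter : number of training iterations (full passes).
    batch_size : mini-batch size; None means full batch.
    init : optional CnnParams to warm-start from (pre-trained weights).
    seed : initialisation / shuffling seed (ignored for init warm starts).
    """

    def __init__(self, lr=0.1, n_iter=25, batch_size=None, init=None, seed=0):
        self.lr = lr
        self.n_iter = n_iter
        self.batch_size = batch_size
        self.init = init
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 4 or X.shape[1:] != GRID_SHAPE:
            raise ValueError(f"X must have shape (n, {GRID_SHAPE})")
        params = self.init.copy() if self.init is not None else cnn_init(self.seed)
        running = params.running

        def forward(tensors, xb, training):
            return cnn_forward(tensors, running, xb, training, update_stats=training)

        tensors, trace = train_sgd(
            forward, params.tensors, X, y,
            lr=self.lr, n_iter=self.n_iter, batch_size=self.batch_size,
            seed=self.seed,
        )
        self.params_ = CnnParams(tensors=tensors, running=running, seed=self.seed)
        self.loss_trace_ = trace
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        p = self.params_
        return cnn_forward(p.tensors, p.running, Tensor(X), training=False).data


class FusionRegressor(BaseEstimator, RegressorMixin):
    """Fusion MLP combining CNN predictions with generator inputs."""

    def __init__(self, lr=0.1, n_iter=100, dropout_rate=0.2, seed=0):
        self.lr = lr
        self.n_iter = n_iter
        self.dropout_rate = dropout_rate
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must have shape (n, 4)")
        params = fusion_init(self.seed, dropout_rate=self.dropout_rate)
        rng = np.random.default_rng(self.seed)

        def forward(tensors, xb, training):
            return fusion_forward(
                tensors, xb, training,
                dropout_rate=self.dropout_rate, rng=rng,
            )

        tensors, trace = train_sgd(
            forward, params.tensors, X, y,
            lr=self.lr, n_iter=self.n_iter, seed=self.seed,
        )
        self.params_ = FusionParams(
            tensors=tensors, dropout_rate=self.dropout_rate, seed=self.seed
        )
        self.loss_trace_ = trace
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        return fusion_forward(self.params_.tensors, Tensor(X), training=False).data
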