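"""Training regimes for per-subject emotion prediction.

Three ways to obtain a subject-specific valence/arousal regressor from a
small amount of that subject's EEG:

* method A — meta-learned initialisation (MAML): treat each participant
  as one task; per outer iteration, adapt a copy of the shared
  initialisation on a 20-piece support set of each task with one inner
  SGD step (learning rate alpha), then update the initialisation with
  the gradient, through the inner step, of the summed query-set losses
  (learning rate beta = 0.1).  Fine-tune on the target subject for 13
  iterations at learning rate 0.1.
* method B — pooled pre-training: all pre-training subjects' windows
  form one pool, trained with mini-batch SGD (batch 1024); fine-tune 10
  iterations at 0.1.
* method C — scratch: train only on the target subject, 25 iterations
  at 0.1.

The meta-gradient is exact (second order): for an inner step
theta' = theta - alpha * g_s(theta), the outer gradient is
(I - alpha * H_s) v with v the query-set gradient at theta', computed
here as v minus alpha times a Hessian-vector product — no first-order
approximation.  A ``second_order=False`` switch drops the curvature
term.

A fusion stage (CNN predictions + music-generator inputs through the
small MLP) can be trained on top of any fitted CNN; per-piece RMSE
evaluation averages the 20 window-level predictions of each piece.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as _feat
from . import nets
from .autodiff import Tensor, add, grad, mul, no_grad, tsum
from .cohort import EmotionPoint, stimulus_grid

__all__ = [
    "FeaturizedTask", "featurize_task", "MamlConfig", "PooledConfig",
    "meta_gradient", "maml_pretrain", "pooled_pretrain", "finetune",
    "train_method", "train_fusion", "evaluate_rmse",
    "cnn_window_predictor", "fusion_window_predictor",
    "MamlPretrainer", "PooledPretrainer",
]

FINETUNE_LR = 0.1
FINETUNE_ITERS = {"A": 13, "B": 10, "C": 25}
FUSION_LR = 0.1
FUSION_ITERS = 100
# CNN fine-tuning "iterations" are full-batch gradient steps on the
# subject's training windows — the same update as the meta-learning
# inner step, of which fine-tuning is a continuation.  The fusion
# network's "iterations" are epochs of shuffled mini-batch SGD: a
# freshly initialised network cannot approach convergence in 100
# full-batch steps at lr 0.1, which would make its fixed budget
# meaningless.
SGD_BATCH_SIZE = 32


# ---------------------------------------------------------------------
# featurized tasks


@dataclass
class FeaturizedTask:
    """One participant's feature tensors and labels, one row per piece."""

    X: np.ndarray          # (n_pieces, n_windows, 6, 6, 5)
    y: np.ndarray          # (n_pieces, 2) SAM labels
    stimuli: list          # generator inputs, one per piece
    participant_id: str = ""

    @property
    def n_pieces(self) -> int:
        return self.X.shape[0]

    def windows(self, piece_idx=None):
        """Window-level (X, y) arrays for the given pieces (default all)."""
        if piece_idx is None:
            piece_idx = np.arange(self.n_pieces)
        piece_idx = np.asarray(piece_idx)
        Xw = self.X[piece_idx].reshape(-1, *self.X.shape[2:])
        yw = np.repeat(self.y[piece_idx], self.X.shape[1], axis=0)
        return Xw, yw

    def piece_indices(self, stimuli) -> np.ndarray:
        """Indices of the given generator inputs; error if any is absent."""
        keys = [(t.valence, t.arousal) for t in self.stimuli]
        out = []
        for s in stimuli:
            k = (s.valence, s.arousal)
            if k not in keys:
                raise ValueError(f"stimulus {k} not among this task's pieces")
            out.append(keys.index(k))
        return np.asarray(out)


def featurize_task(task, channel_map=None) -> FeaturizedTask:
    """Run the feature pipeline over a TaskDataset."""
    cm = channel_map or _feat.default_channel_map()
    X = _feat.batch_trial_feature_tensors(task.trials, cm)
    y = np.stack([t.sam_label.as_array() for t in task.trials], axis=0)
    return FeaturizedTask(
        X=X, y=y,
        stimuli=[t.generator_input for t in task.trials],
        participant_id=task.participant.participant_id,
    )


# ---------------------------------------------------------------------
# meta-gradient


def meta_gradient(forward, tensors, tasks, inner_lr, second_order=True):
    """Exact gradient of the summed post-adaptation query losses.

    Parameters
    ----------
    forward : callable(tensors, X, training) -> prediction Tensor.
    tensors : list of parameter Tensors (the shared initialisation).
    tasks : iterable of (X_support, y_support, X_query, y_query) arrays.
    inner_lr : inner-step learning rate alpha.
    second_order : include the curvature (Hessian-vector) term.

    Returns
    -------
    (grads, mean_query_loss) : list of numpy arrays (one per tensor) and
    the mean of the per-task post-adaptation query losses.
    """
    total = [np.zeros_like(t.data) for t in tensors]
    losses = []
    for Xs, ys, Xq, yq in tasks:
        loss_s = nets.mse_loss(forward(tensors, Tensor(np.asarray(Xs, float)), True), ys)
        g_sup = grad(loss_s, tensors, create_graph=second_order)
        adapted = [
            Tensor(t.data - inner_lr * g.data, requires_grad=True)
            for t, g in zip(tensors, g_sup)
        ]
        loss_q = nets.mse_loss(forward(adapted, Tensor(np.asarray(Xq, float)), True), yq)
        v = grad(loss_q, adapted)
        losses.append(float(loss_q.data))
        if second_order and inner_lr != 0.0:
            # chain rule through theta' = theta - alpha*g_s: J^T v = v - alpha*H_s v
            inner = None
            for gj, vj in zip(g_sup, v):
                term = tsum(mul(gj, Tensor(vj.data)))
                inner = term if inner is None else add(inner, term)
            hv = grad(inner, tensors)
            for acc, vj, hj in zip(total, v, hv):
                acc += vj.data - inner_lr * hj.data
        else:
            for acc, vj in zip(total, v):
                acc += vj.data
    return total, float(np.mean(losses))


# ---------------------------------------------------------------------
# pre-training


@dataclass
class MamlConfig:
    inner_lrs: tuple = (0.1, 0.01)
    outer_lr: float = 0.1
    support_size: int = 20
    patience: int = 5           # counted in validation checks
    max_iter: int = 60
    val_every: int = 1          # validate every k-th meta-iteration
    # Scale applied to the weight matrices of the starting point.  Batch
    # norm makes the network function invariant to conv-weight scale,
    # but the effective SGD step on a weight's *direction* shrinks as
    # its norm grows; starting meta-training from a scaled-down init
    # removes an otherwise long mean-prediction plateau under plain SGD.
    init_scale: float = 0.3
    second_order: bool = True
    seed: int = 0


@dataclass
class PooledConfig:
    lrs: tuple = (0.1, 0.01)
    batch_size: int = 1024
    patience: int = 5
    max_iter: int = 60
    seed: int = 0


def _split_support_query(n_pieces, support_size, rng):
    perm = rng.permutation(n_pieces)
    return perm[:support_size], perm[support_size:]


def _val_meta_loss(forward, tensors, val_splits, inner_lr):
    """Mean post-adaptation query loss over validation tasks (fixed splits)."""
    losses = []
    for Xs, ys, Xq, yq in val_splits:
        loss_s = nets.mse_loss(forward(tensors, Tensor(Xs), True), ys)
        g_sup = grad(loss_s, tensors)
        adapted = [
            Tensor(t.data - inner_lr * g.data) for t, g in zip(tensors, g_sup)
        ]
        with no_grad():
            loss_q = nets.mse_loss(forward(adapted, Tensor(Xq), True), yq)
        losses.append(float(loss_q.data))
    return float(np.mean(losses))


def _maml_train_one(tasks, val_splits, inner_lr, cfg) -> tuple:
    params = nets.cnn_init(cfg.seed)
    for t in params.tensors:
        if t.data.ndim == 2:
            t.data = t.data * cfg.init_scale
    running = params.running

    def forward(tensors, x, training):
        return nets.cnn_forward(tensors, running, x, training)

    rng = np.random.default_rng(cfg.seed + 1)
    tensors = params.tensors
    best = (np.inf, [t.data.copy() for t in tensors])
    since_best = 0
    for it in range(cfg.max_iter):
        batches = []
        for ft in tasks:
            sup, qry = _split_support_query(ft.n_pieces, cfg.support_size, rng)
            Xs, ys = ft.windows(sup)
            Xq, yq = ft.windows(qry)
            batches.append((Xs, ys, Xq, yq))
        grads, _ = meta_gradient(
            forward, tensors, batches, inner_lr, cfg.second_order
        )
        # outer step on the mean task gradient: with a summed gradient
        # the effective step would grow with the number of tasks, which
        # empirically stalls plain SGD on a mean-prediction plateau
        for t, g in zip(tensors, grads):
            t.data = t.data - cfg.outer_lr * g / len(batches)
        if (it + 1) % cfg.val_every and it + 1 < cfg.max_iter:
            continue
        vl = _val_meta_loss(forward, tensors, val_splits, inner_lr)
        if vl < best[0]:
            best = (vl, [t.data.copy() for t in tensors])
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.patience:
                break
    out = nets.CnnParams(
        tensors=[Tensor(d, requires_grad=True) for d in best[1]],
        running=running, seed=cfg.seed,
    )
    return out, best[0]


def maml_pretrain(tasks, val_tasks, cfg: MamlConfig | None = None):
    """Meta-train an initialisation over participant-tasks.

    The inner learning rate is selected from ``cfg.inner_lrs`` by the
    validation meta-loss (adapt on a fixed 20-piece support split of
    each validation task, evaluate on its query pieces).

    Returns ``(CnnParams, info)`` with the chosen hyperparameter in info.
    """
    cfg = cfg or MamlConfig()
    if len(tasks) < 2:
        raise ValueError("need at least two pre-training tasks")
    for ft in tasks:
        if ft.n_pieces <= cfg.support_size:
            raise ValueError(
                f"task with {ft.n_pieces} pieces cannot supply a "
                f"{cfg.support_size}-piece support set plus a query set"
            )
    val_rng = np.random.default_rng(cfg.seed + 2)
    val_splits = []
    for ft in val_tasks:
        sup, qry = _split_support_query(ft.n_pieces, cfg.support_size, val_rng)
        Xs, ys = ft.windows(sup)
        Xq, yq = ft.windows(qry)
        val_splits.append((Xs, ys, Xq, yq))

    best_params, best_val, best_lr = None, np.inf, None
    for inner_lr in cfg.inner_lrs:
        params, vl = _maml_train_one(tasks, val_splits, inner_lr, cfg)
        if vl < best_val:
            best_params, best_val, best_lr = params, vl, inner_lr
    return best_params, {"inner_lr": best_lr, "val_loss": best_val}


def pooled_pretrain(tasks, val_tasks, cfg: PooledConfig | None = None):
    """Pre-train on all subjects' windows pooled into one dataset."""
    cfg = cfg or PooledConfig()
    if not tasks:
        raise ValueError("empty pre-training pool")
    Xp = np.concatenate([ft.windows()[0] for ft in tasks], axis=0)
    yp = np.concatenate([ft.windows()[1] for ft in tasks], axis=0)
    Xv = np.concatenate([ft.windows()[0] for ft in val_tasks], axis=0)
    yv = np.concatenate([ft.windows()[1] for ft in val_tasks], axis=0)

    best_params, best_val, best_lr = None, np.inf, None
    for lr in cfg.lrs:
        params = nets.cnn_init(cfg.seed)
        running = params.running

        def forward(tensors, x, training):
            return nets.cnn_forward(tensors, running, x, training, update_stats=training)

        tensors, _ = nets.train_sgd(
            forward, params.tensors, Xp, yp, lr=lr,
            n_iter=cfg.max_iter, batch_size=cfg.batch_size,
            val=(Xv, yv), patience=cfg.patience, seed=cfg.seed,
            max_iter=cfg.max_iter,
        )
        out = nets.CnnParams(tensors=tensors, running=running, seed=cfg.seed)
        with no_grad():
            vl = float(nets.mse_loss(
                nets.cnn_forward(out.tensors, out.running, Tensor(Xv), False), yv
            ).data)
        if vl < best_val:
            best_params, best_val, best_lr = out, vl, lr
    return best_params, {"lr": best_lr, "val_loss": best_val}


# ---------------------------------------------------------------------
# fine-tuning and fusion


def _training_pieces(ftask: FeaturizedTask, pieces):
    if isinstance(pieces, int):
        pieces = stimulus_grid(f"train{pieces}")
    return ftask.piece_indices(pieces), pieces


def finetune(
    init: nets.CnnParams,
    ftask: FeaturizedTask,
    pieces,
    lr: float = FINETUNE_LR,
    n_iter: int = 13,
    seed: int = 0,
) -> nets.CnnParams:
    """Fixed-iteration SGD on the target subject's training pieces.

    ``pieces`` is one of {5, 9, 13, 25} or an explicit stimulus list; it
    must be a subset of the task's stimuli.  Runs exactly ``n_iter``
    full-batch gradient steps (no early stopping), then freezes the
    batch-normalisation running statistics on the training batch so that
    single-window inference is consistent with training.
    """
    idx, _ = _training_pieces(ftask, pieces)
    X, y = ftask.windows(idx)
    params = init.copy()
    running = params.running

    def forward(tensors, x, training):
        return nets.cnn_forward(tensors, running, x, training)

    tensors, trace = nets.train_sgd(
        forward, params.tensors, X, y, lr=lr, n_iter=n_iter, seed=seed
    )
    out = nets.CnnParams(tensors=tensors, running=running, seed=init.seed)
    nets.refresh_bn_stats(out, X)
    out.loss_trace = trace
    return out


def train_method(
    method: str,
    ftask: FeaturizedTask,
    pieces,
    maml_init: nets.CnnParams | None = None,
    pooled_init: nets.CnnParams | None = None,
    seed: int = 0,
) -> nets.CnnParams:
    """Train the target-subject CNN under one of the three regimes."""
    if method == "A":
        if maml_init is None:
            raise ValueError("method A needs a meta-learned initialisation")
        return finetune(maml_init, ftask, pieces, n_iter=FINETUNE_ITERS["A"], seed=seed)
    if method == "B":
        if pooled_init is None:
            raise ValueError("method B needs a pooled initialisation")
        return finetune(pooled_init, ftask, pieces, n_iter=FINETUNE_ITERS["B"], seed=seed)
    if method == "C":
        return finetune(
            nets.cnn_init(seed), ftask, pieces, n_iter=FINETUNE_ITERS["C"], seed=seed
        )
    raise ValueError(f"unknown method {method!r}")


def cnn_window_predictor(params: nets.CnnParams):
    """Window-level inference function (X -> (n, 2)) for a fitted CNN."""

    def predict(X):
        with no_grad():
            return nets.cnn_forward(
                params.tensors, params.running, Tensor(np.asarray(X, float)), False
            ).data

    return predict


def fusion_window_predictor(cnn: nets.CnnParams, fusion: nets.FusionParams):
    """Window-level inference for CNN + fusion; CNN outputs are clipped
    to [0,1] before entering the fusion network."""
    cnn_pred = cnn_window_predictor(cnn)

    def predict(X, gen_inputs):
        p = np.clip(cnn_pred(X), 0.0, 1.0)
        xf = np.concatenate([p, np.asarray(gen_inputs, float)], axis=1)
        with no_grad():
            return nets.fusion_forward(fusion.tensors, Tensor(xf), False).data

    return predict


def train_fusion(
    cnn: nets.CnnParams,
    ftask: FeaturizedTask,
    pieces,
    lr: float = FUSION_LR,
    n_iter: int = FUSION_ITERS,
    seed: int = 0,
) -> nets.FusionParams:
    """Train the fusion MLP on (clipped CNN prediction, generator input).

    The CNN is frozen; only the 4->8->2 network is updated.
    """
    idx, _ = _training_pieces(ftask, pieces)
    X, y = ftask.windows(idx)
    gen = np.repeat(
        np.stack([ftask.stimuli[i].as_array() for i in idx]), ftask.X.shape[1], axis=0
    )
    cnn_preds = np.clip(cnn_window_predictor(cnn)(X), 0.0, 1.0)
    Xf = np.concatenate([cnn_preds, gen], axis=1)

    params = nets.fusion_init(seed)
    rng = np.random.default_rng(seed)

    def forward(tensors, x, training):
        return nets.fusion_forward(
            tensors, x, training, dropout_rate=params.dropout_rate, rng=rng
        )

    tensors, trace = nets.train_sgd(
        forward, params.tensors, Xf, y, lr=lr, n_iter=n_iter,
        batch_size=SGD_BATCH_SIZE, seed=seed,
    )
    out = nets.FusionParams(tensors=tensors, dropout_rate=params.dropout_rate, seed=seed)
    out.loss_trace = trace
    return out


# ---------------------------------------------------------------------
# evaluation


def evaluate_rmse(model, ftask: FeaturizedTask, pieces) -> tuple:
    """Per-axis RMSE over test pieces.

    ``model`` is a CnnParams or a (CnnParams, FusionParams) pair.  The
    per-piece prediction is the mean of the 20 window-level predictions.
    Returns (rmse_valence, rmse_arousal).
    """
    idx = ftask.piece_indices(pieces)
    if len(idx) == 0:
        raise ValueError("empty test set")
    if isinstance(model, tuple):
        cnn, fusion = model
        predict = fusion_window_predictor(cnn, fusion)
        use_gen = True
    else:
        predict = cnn_window_predictor(model)
        use_gen = False
    preds, labels = [], []
    for i in idx:
        Xw = ftask.X[i]
        if use_gen:
            gen = np.tile(ftask.stimuli[i].as_array(), (Xw.shape[0], 1))
            pw = predict(Xw, gen)
        else:
            pw = predict(Xw)
        preds.append(pw.mean(axis=0))
        labels.append(ftask.y[i])
    preds = np.stack(preds)
    labels = np.stack(labels)
    rmse = np.sqrt(((preds - labels) ** 2).mean(axis=0))
    return float(rmse[0]), float(rmse[1])


def generator_input_rmse(ftask: FeaturizedTask, pieces) -> tuple:
    """RMSE of predicting the label by the generator input itself."""
    idx = ftask.piece_indices(pieces)
    gen = np.stack([ftask.stimuli[i].as_array() for i in idx])
    lab = ftask.y[idx]
    rmse = np.sqrt(((gen - lab) ** 2).mean(axis=0))
    return float(rmse[0]), float(rmse[1])


# ---------------------------------------------------------------------
# estimator-style wrappers


class MamlPretrainer:
    """Estimator-style wrapper around :func:`maml_pretrain`."""

    def __init__(self, cfg: MamlConfig | None = None):
        self.cfg = cfg or MamlConfig()

    def fit(self, tasks, val_tasks):
        self.params_, self.info_ = maml_pretrain(tasks, val_tasks, self.cfg)
        return self


class PooledPretrainer:
    """Estimator-style wrapper around :func:`pooled_pretrain`."""

    def __init__(self, cfg: PooledConfig | None = None):
        self.cfg = cfg or PooledConfig()

    def fit(self, tasks, val_tasks):
        self.params_, self.info_ = pooled_pretrain(tasks, val_tasks, self.cfg)
        return self
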