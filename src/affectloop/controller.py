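"""Closed-loop control of the music generator's (valence, arousal) inputs.

A 20-measure piece is generated in five four-measure blocks.  Before the
music starts (update counter s = 0) the listener's emotion is predicted
from 1 s of silent-state EEG; during each block a 1-s EEG window taken
at the start of the block yields the current predicted emotion, and the
generator input for the next block is chosen by one of three policies:

* iso-principle (A): interpolate intermediate targets from the
  pre-listening prediction pred(0) to the target, and correct each next
  input by half the gap between the previous intermediate target and
  the current prediction::

      mid_target(s+1) = pred(0) + s * (target - pred(0)) / (s_max - 1)
      input(s+1)      = mid_target(s+1) + 0.5 * (mid_target(s) - pred(s))

  with mid_target(1) = pred(0) and input(1) = mid_target(1);
* direct feedback (B): start at the target and add half the remaining
  error, input(s+1) = input(s) + 0.5 * (target - pred(s));
* fixed (C): always input the target, ignoring predictions.

Updates run for s = 0 .. s_max-1 with s_max = 5, each axis handled
independently; every *emitted* input is clipped to [0, 1] (intermediate
targets are stored unclipped so the interpolation reaches the target
exactly).  A session's quality is the Euclidean distance between the
target and the final predicted emotion pred(s_max).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import features as _feat
from .autodiff import Tensor, no_grad
from . import nets
from .cohort import EmotionPoint, ParticipantModel, felt_emotion, simulate_window

__all__ = [
    "S_MAX", "ControllerState", "SessionResult", "SessionConfig",
    "clip01", "distance", "iso_update", "direct_update", "fixed_update",
    "next_input", "ModelPredictor", "run_session", "POLICIES",
]

S_MAX = 5
POLICIES = ("A_iso", "B_direct", "C_fixed")


def clip01(p) -> np.ndarray:
    """Clip a (valence, arousal) pair to the unit square."""
    if isinstance(p, EmotionPoint):
        p = p.as_array()
    return np.clip(np.asarray(p, dtype=float), 0.0, 1.0)


def distance(target, pred_final) -> float:
    """Euclidean distance between target and final predicted emotion."""
    t = target.as_array() if isinstance(target, EmotionPoint) else np.asarray(target, float)
    p = (
        pred_final.as_array()
        if isinstance(pred_final, EmotionPoint)
        else np.asarray(pred_final, float)
    )
    return float(np.sqrt(((t - p) ** 2).sum()))


@dataclass
class ControllerState:
    """Per-session trajectory, indexed by the update counter s.

    ``preds[s]`` is the prediction at update s (s = 0 is the silent-state
    prediction); ``inputs[s]`` is the generator input emitted for block s
    (1-based; index 0 is None); ``mid_targets`` likewise holds the
    iso-principle intermediate targets (policy A only).
    """

    target: np.ndarray
    s_max: int = S_MAX
    s: int = 0
    preds: list = field(default_factory=list)        # preds[s], s = 0..s_max
    inputs: list = field(default_factory=lambda: [None])   # inputs[s], s = 1..s_max
    mid_targets: list = field(default_factory=lambda: [None])

    def __post_init__(self):
        self.target = np.asarray(self.target, dtype=float)

    @property
    def pred0(self) -> np.ndarray:
        return np.asarray(self.preds[0], float)

    def _check(self):
        if self.s >= self.s_max:
            raise ValueError(f"no more updates: s={self.s} >= s_max={self.s_max}")
        if not self.preds:
            raise ValueError("pred(0) must be recorded before updating")


def iso_update(state: ControllerState) -> np.ndarray:
    """Next input under the iso principle; advances the state."""
    state._check()
    s = state.s
    p0 = state.pred0
    if s == 0:
        mid = p0.copy()
    else:
        # convex-combination form: exact at both endpoints (w=0 -> pred(0),
        # w=1 -> target), unlike p0 + s*(target-p0)/(s_max-1)
        w = s / (state.s_max - 1)
        mid = (1.0 - w) * p0 + w * state.target
    state.mid_targets.append(mid)
    if s == 0:
        nxt = mid.copy()
    else:
        prev_mid = np.asarray(state.mid_targets[s], float)
        pred_s = np.asarray(state.preds[s], float)
        nxt = mid + 0.5 * (prev_mid - pred_s)
    nxt = clip01(nxt)
    state.inputs.append(nxt)
    state.s += 1
    return nxt


def direct_update(state: ControllerState) -> np.ndarray:
    """Next input under direct feedback; advances the state."""
    state._check()
    s = state.s
    if s == 0:
        nxt = state.target.copy()
    else:
        prev = np.asarray(state.inputs[s], float)
        pred_s = np.asarray(state.preds[s], float)
        nxt = prev + 0.5 * (state.target - pred_s)
    nxt = clip01(nxt)
    state.inputs.append(nxt)
    state.s += 1
    return nxt


def fixed_update(state: ControllerState) -> np.ndarray:
    """Next input with the target held fixed; advances the state."""
    state._check()
    nxt = clip01(state.target.copy())
    state.inputs.append(nxt)
    state.s += 1
    return nxt


_UPDATES = {"A_iso": iso_update, "B_direct": direct_update, "C_fixed": fixed_update}


def next_input(policy: str, state: ControllerState) -> np.ndarray:
    try:
        return _UPDATES[policy](state)
    except KeyError:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}") from None


# ---------------------------------------------------------------------
# model-driven prediction inside a session


class ModelPredictor:
    """Feature pipeline + trained models, as used inside a session.

    The silent-state prediction uses the CNN alone (no generator input
    exists yet); in-music predictions feed the clipped CNN output and the
    current generator input through the fusion network.  Predictions
    returned to the controller are clipped to [0, 1].
    """

    def __init__(self, cnn: nets.CnnParams, fusion: nets.FusionParams | None = None,
                 channel_map=None, fs: float = 100.0):
        self.cnn = cnn
        self.fusion = fusion
        self.channel_map = channel_map or _feat.default_channel_map()
        self.fs = fs
        self._baseline = None

    def _features(self, window: np.ndarray) -> np.ndarray:
        win = window[None, :, :]
        return _feat.logvar_features(win, self.fs, self.channel_map.selected_channels,
                                     self.channel_map)[0]

    def set_baseline(self, baseline_windows) -> None:
        """Store the mean feature vector of the silent baseline windows."""
        rows = [self._features(w) for w in baseline_windows]
        self._baseline = np.mean(rows, axis=0)

    def _grid(self, window: np.ndarray) -> np.ndarray:
        if self._baseline is None:
            raise ValueError("set_baseline must be called before predicting")
        row = self._features(window) - self._baseline
        return _feat.to_grid(row, self.channel_map)

    def predict_silence(self, window: np.ndarray) -> np.ndarray:
        grid = self._grid(window)[None]
        with no_grad():
            p = nets.cnn_forward(
                self.cnn.tensors, self.cnn.running, Tensor(grid), False
            ).data[0]
        return clip01(p)

    def predict_music(self, window: np.ndarray, gen_input: np.ndarray) -> np.ndarray:
        if self.fusion is None:
            raise ValueError("this predictor has no fusion network")
        grid = self._grid(window)[None]
        with no_grad():
            cp = nets.cnn_forward(
                self.cnn.tensors, self.cnn.running, Tensor(grid), False
            ).data
            xf = np.concatenate([np.clip(cp, 0, 1), np.asarray(gen_input, float)[None]], axis=1)
            p = nets.fusion_forward(self.fusion.tensors, Tensor(xf), False).data[0]
        return clip01(p)


@dataclass(frozen=True)
class SessionConfig:
    """Timing of one induction session (seconds; silence precedes music)."""

    fs: float = 100.0
    silence_duration: float = 10.0
    baseline_start: float = 2.0    # baseline windows span 2-5 s of silence
    baseline_windows: int = 3
    pred0_start: float = 5.0       # silent-state prediction window at 5-6 s
    n_blocks: int = S_MAX          # five four-measure blocks of a 20-measure piece


@dataclass
class SessionResult:
    policy: str
    state: ControllerState
    final_distance: float
    n_input_updates: int
    n_music_predictions: int


def run_session(
    participant: ParticipantModel,
    predictor,
    policy: str,
    target,
    seed: int = 0,
    config: SessionConfig | None = None,
) -> SessionResult:
    """Simulate one closed-loop induction session.

    The participant rests at their resting emotion during silence; during
    each music block their felt emotion is the affine response to the
    block's generator input.  A per-session band/channel log-power offset
    (the analogue of per-trial noise) is shared by every window, so the
    baseline correction removes it.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {POLICIES}")
    if policy in ("A_iso", "B_direct") and getattr(predictor, "fusion", True) is None:
        raise ValueError(f"policy {policy} requires a fusion model")
    cfg = config or SessionConfig()
    rng = np.random.default_rng(seed)
    session_noise = rng.normal(
        0.0, participant.noise_scale,
        size=(len(_feat.BANDS), participant.n_channels),
    )

    def window(felt):
        return simulate_window(
            participant, felt, cfg.fs, rng, noise=session_noise
        )

    rest = participant.rest_emotion
    baseline = [window(rest) for _ in range(cfg.baseline_windows)]
    predictor.set_baseline(baseline)
    pred0 = predictor.predict_silence(window(rest))

    state = ControllerState(target=clip01(target), s_max=cfg.n_blocks)
    state.preds.append(np.asarray(pred0, float))
    n_music_preds = 0
    for _ in range(cfg.n_blocks):
        gen_input = next_input(policy, state)
        felt = felt_emotion(participant, EmotionPoint.from_array(gen_input))
        pred = predictor.predict_music(window(felt), gen_input)
        state.preds.append(np.asarray(pred, float))
        n_music_preds += 1

    final = distance(state.target, state.preds[-1])
    return SessionResult(
        policy=policy,
        state=state,
        final_distance=final,
        n_input_updates=len(state.inputs) - 1,
        n_music_predictions=n_music_preds,
    )
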