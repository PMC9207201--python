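"""Unit tests for the closed-loop music-input controller."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import affectloop as al
from affectloop import nets
from affectloop.controller import (
    POLICIES, S_MAX, ControllerState, ModelPredictor, clip01, direct_update,
    distance, fixed_update, iso_update, next_input, run_session,
)

unit = st.floats(0.0, 1.0)
anyval = st.floats(-10.0, 10.0)


def _state(target, pred0, s_max=S_MAX):
    s = ControllerState(target=np.asarray(target, float), s_max=s_max)
    s.preds.append(np.asarray(pred0, float))
    return s


# ---------------------------------------------------------------- algebra


@given(pv=unit, pa=unit, tv=unit, ta=unit)
def test_iso_endpoints(pv, pa, tv, ta):
    """mid_target(1) = pred(0) and mid_target(5) = target, exactly."""
    state = _state([tv, ta], [pv, pa])
    rng = np.random.default_rng(0)
    for _ in range(S_MAX):
        iso_update(state)
        state.preds.append(rng.uniform(-2, 3, 2))  # adversarial predictions
    np.testing.assert_array_equal(state.mid_targets[1], [pv, pa])
    np.testing.assert_array_equal(state.mid_targets[S_MAX], [tv, ta])


@given(pv=unit, pa=unit, tv=unit, ta=unit,
       preds=st.lists(st.tuples(anyval, anyval), min_size=S_MAX, max_size=S_MAX))
def test_all_policies_emit_inputs_in_unit_square(pv, pa, tv, ta, preds):
    for policy in POLICIES:
        state = _state([tv, ta], [pv, pa])
        for k in range(S_MAX):
            out = next_input(policy, state)
            assert np.all(out >= 0.0) and np.all(out <= 1.0)
            state.preds.append(np.asarray(preds[k], float))
        assert len(state.inputs) - 1 == S_MAX


def test_iso_first_input_is_pred0():
    state = _state([1.0, 0.0], [0.25, 0.5])
    out = iso_update(state)
    np.testing.assert_array_equal(out, [0.25, 0.5])


def test_iso_correction_term_hand_example():
    # pred0=(0,0), target=(1,1): mid(2) = (0.25, 0.25); if pred(1)=(0.05,0.05),
    # input(2) = mid(2) + 0.5*(mid(1) - pred(1)) = 0.25 + 0.5*(0 - 0.05)
    state = _state([1.0, 1.0], [0.0, 0.0])
    iso_update(state)
    state.preds.append(np.array([0.05, 0.05]))
    out = iso_update(state)
    np.testing.assert_allclose(out, [0.225, 0.225])


def test_direct_update_hand_example():
    state = _state([1.0, 0.0], [0.5, 0.5])
    first = direct_update(state)
    np.testing.assert_array_equal(first, [1.0, 0.0])  # starts at target
    state.preds.append(np.array([0.8, 0.4]))
    out = direct_update(state)
    # input(2) = input(1) + 0.5*(target - pred(1)) = (1.1, -0.2) clipped
    np.testing.assert_allclose(out, [1.0, 0.0])


def test_fixed_update_always_target():
    state = _state([0.3, 0.7], [0.9, 0.1])
    for _ in range(S_MAX):
        np.testing.assert_array_equal(fixed_update(state), [0.3, 0.7])
        state.preds.append(np.array([0.0, 0.0]))


def test_axis_separability():
    """Each axis is controlled independently: permuting the axes of all
    inputs permutes the outputs."""
    state_a = _state([0.9, 0.2], [0.1, 0.6])
    state_b = _state([0.2, 0.9], [0.6, 0.1])
    for _ in range(S_MAX):
        out_a = iso_update(state_a)
        out_b = iso_update(state_b)
        np.testing.assert_allclose(out_a, out_b[::-1])
        state_a.preds.append(np.array([0.3, 0.4]))
        state_b.preds.append(np.array([0.4, 0.3]))


def test_update_guards():
    state = _state([0.5, 0.5], [0.5, 0.5])
    for _ in range(S_MAX):
        fixed_update(state)
        state.preds.append(np.zeros(2))
    with pytest.raises(ValueError, match="no more updates"):
        fixed_update(state)
    empty = ControllerState(target=np.array([0.5, 0.5]))
    with pytest.raises(ValueError, match="pred\\(0\\)"):
        iso_update(empty)
    with pytest.raises(ValueError, match="unknown policy"):
        next_input("Z", _state([0, 0], [0, 0]))


def test_distance_is_euclidean():
    assert distance(np.array([0.0, 0.0]), np.array([1.0, 1.0])) == math.sqrt(2.0)
    assert distance(al.EmotionPoint(0.5, 0.5), al.EmotionPoint(0.5, 0.5)) == 0.0


@given(x=st.tuples(anyval, anyval))
def test_clip01(x):
    out = clip01(np.asarray(x))
    assert np.all(out >= 0) and np.all(out <= 1)


# ----------------------------------------------------------- session loop


@pytest.fixture(scope="module")
def predictor():
    return ModelPredictor(nets.cnn_init(0), nets.fusion_init(0))


def test_run_session_bookkeeping(participant, predictor):
    res = run_session(participant, predictor, "B_direct",
                      al.EmotionPoint(0.875, 0.875), seed=1)
    assert res.n_input_updates == S_MAX
    assert res.n_music_predictions == S_MAX
    assert len(res.state.preds) == S_MAX + 1
    assert res.final_distance == distance(res.state.target, res.state.preds[-1])
    for inp in res.state.inputs[1:]:
        assert np.all(inp >= 0) and np.all(inp <= 1)


def test_run_session_deterministic(participant, predictor):
    r1 = run_session(participant, predictor, "A_iso", al.EmotionPoint(0.5, 0.5), seed=7)
    r2 = run_session(participant, predictor, "A_iso", al.EmotionPoint(0.5, 0.5), seed=7)
    assert r1.final_distance == r2.final_distance
    for a, b in zip(r1.state.preds, r2.state.preds):
        np.testing.assert_array_equal(a, b)


def test_run_session_policy_guards(participant):
    cnn_only = ModelPredictor(nets.cnn_init(0), None)
    with pytest.raises(ValueError, match="fusion"):
        run_session(participant, cnn_only, "A_iso", al.EmotionPoint(0.5, 0.5))
    with pytest.raises(ValueError, match="unknown policy"):
        run_session(participant, cnn_only, "nope", al.EmotionPoint(0.5, 0.5))


def test_perfect_loop_with_oracle_predictor(participant):
    """With an identity affect mapping, no noise, and an oracle predictor
    that reports the felt emotion exactly, policies A and C both land on
    the target; the A trajectory interpolates while C jumps."""
    p = dataclasses.replace(
        participant,
        affect_gain=np.ones(2), affect_offset=np.zeros(2),
        label_noise=0.0, rest_emotion=np.array([0.2, 0.2]),
    )

    class Oracle:
        fusion = object()   # pass the has-fusion check
        def __init__(self):
            self._felt = p.rest_emotion

        def set_baseline(self, windows):
            pass

        def predict_silence(self, window):
            return p.rest_emotion.copy()

        def predict_music(self, window, gen_input):
            return al.felt_emotion(p, al.EmotionPoint.from_array(gen_input))

    target = al.EmotionPoint(0.875, 0.875)
    res_a = run_session(p, Oracle(), "A_iso", target, seed=0)
    res_c = run_session(p, Oracle(), "C_fixed", target, seed=0)
    assert res_a.final_distance < 1e-9
    assert res_c.final_distance < 1e-9
    # A interpolates: its first input stays at the resting emotion
    np.testing.assert_allclose(res_a.state.inputs[1], p.rest_emotion)
    np.testing.assert_allclose(res_c.state.inputs[1], target.as_array())


def test_model_predictor_requires_baseline(participant):
    pred = ModelPredictor(nets.cnn_init(0), nets.fusion_init(0))
    with pytest.raises(ValueError, match="set_baseline"):
        pred.predict_silence(np.zeros((14, 100)))
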