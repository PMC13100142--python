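"""Tests for the sequence encoding, the gated cell, and both classifiers."""

import math

import numpy as np
import pytest

from biruni import (
    LSTMParams,
    LSTMState,
    SequenceEncoding,
    TrainConfig,
    TrainedModel,
    forward,
    lstm_cell,
    predict_lstm,
    predict_mlp,
    reshape_to_sequence,
    train_lstm,
    train_mlp,
)
from biruni.lstm_mlp import _backward_batch, _forward_batch


def sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def zero_params(h, m, candidate="sigmoid"):
    return LSTMParams(
        W_f=np.zeros((h, h + m)), W_i=np.zeros((h, h + m)),
        W_o=np.zeros((h, h + m)), W_c=np.zeros((h, h + m)),
        b_f=np.zeros(h), b_i=np.zeros(h), b_o=np.zeros(h), b_c=np.zeros(h),
        w_out=np.zeros(h), b_out=0.0, candidate_activation=candidate,
    )


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

def test_reshape_identity_ordering_and_round_trip():
    v = np.array([1.0, 2.0, 3.0, 4.0])
    seq = reshape_to_sequence(v, SequenceEncoding(4, 1))
    assert seq.shape == (4, 1)
    assert np.array_equal(seq.ravel(), v)

    rng = np.random.default_rng(3)
    for l, m in [(3, 2), (2, 5), (10, 1)]:
        w = rng.normal(size=l * m)
        assert np.array_equal(
            reshape_to_sequence(w, SequenceEncoding(l, m)).ravel(), w
        )

    seq = reshape_to_sequence(np.arange(1.0, 7.0), SequenceEncoding(3, 2))
    assert np.array_equal(seq, [[1, 2], [3, 4], [5, 6]])  # row-major pairs

    with pytest.raises(ValueError):
        reshape_to_sequence(np.ones(5), SequenceEncoding(3, 2))
    with pytest.raises(ValueError):
        SequenceEncoding.for_dimension(10, 3)


# ---------------------------------------------------------------------------
# Cell oracles
# ---------------------------------------------------------------------------

def test_zero_parameter_closed_form():
    """All-zero weights: gates 0.5, candidate 0.5, C1 = 0.25,
    y1 = 0.5*tanh(0.25)."""
    p = zero_params(3, 2)
    st = lstm_cell(np.array([5.0, -1.0]), LSTMState.zero(3), p)
    assert np.allclose(st.cell, 0.25, atol=1e-12)
    assert np.allclose(st.output, 0.5 * math.tanh(0.25), atol=1e-12)
    assert st.output[0] == pytest.approx(0.122459, abs=1e-6)


def test_forget_gate_saturation():
    """Large negative forget bias erases the previous cell: C_t -> C*_t o i_t."""
    p = zero_params(2, 1)
    p.b_f[:] = -50.0
    prev = LSTMState(cell=np.array([7.0, -3.0]), output=np.zeros(2))
    st = lstm_cell(np.array([0.0]), prev, p)
    assert np.allclose(st.cell, 0.5 * 0.5, atol=1e-9)  # candidate*input only


def test_one_dimensional_hand_trace():
    """H=1, m=1, all weights [1,1], biases 0, x=1: every gate is sigma(1),
    C1 = sigma(1)^2, y1 = sigma(1)*tanh(C1).  Agreement to 1e-9."""
    p = LSTMParams(
        W_f=np.array([[1.0, 1.0]]), W_i=np.array([[1.0, 1.0]]),
        W_o=np.array([[1.0, 1.0]]), W_c=np.array([[1.0, 1.0]]),
        b_f=np.zeros(1), b_i=np.zeros(1), b_o=np.zeros(1), b_c=np.zeros(1),
        w_out=np.zeros(1), b_out=0.0,
    )
    st = lstm_cell(np.array([1.0]), LSTMState.zero(1), p)
    g = sigmoid(1.0)
    assert g == pytest.approx(0.731059, abs=1e-6)
    assert st.cell[0] == pytest.approx(g * g, abs=1e-9)
    assert st.cell[0] == pytest.approx(0.534447, abs=1e-6)
    assert st.output[0] == pytest.approx(g * math.tanh(g * g), abs=1e-9)


def test_cell_shape_mismatch():
    with pytest.raises(ValueError):
        lstm_cell(np.ones(3), LSTMState.zero(2), zero_params(2, 1))


def test_gate_range_and_cell_bound():
    """Random parameters: gates strictly in (0,1); with sigmoid candidate and
    C_0 = 0, every component of C_t stays in [0, t]."""
    rng = np.random.default_rng(8)
    h, m, steps = 4, 3, 7
    p = LSTMParams.initialize(h, m, seed=1)
    # widen the weights so gates are well away from 0.5
    for w in (p.W_f, p.W_i, p.W_o, p.W_c):
        w *= 5.0
    state = LSTMState.zero(h)
    for t in range(1, steps + 1):
        state = lstm_cell(rng.normal(size=m), state, p)
        assert np.all(state.cell >= 0.0)
        assert np.all(state.cell <= t + 1e-12)
        assert np.all(np.abs(state.output) < 1.0)


# ---------------------------------------------------------------------------
# Forward pass
# ---------------------------------------------------------------------------

def test_forward_symmetric_logit_and_range():
    p = zero_params(4, 2)
    seq = np.random.default_rng(0).normal(size=(5, 2))
    assert forward(seq, p) == 0.5
    p2 = LSTMParams.initialize(4, 2, seed=2)
    prob = forward(seq, p2)
    assert 0.0 < prob < 1.0
    with pytest.raises(ValueError):
        forward(np.empty((0, 2)), p2)


def test_forward_single_step_composition():
    p = LSTMParams.initialize(3, 2, seed=5)
    x = np.array([0.3, -1.2])
    st = lstm_cell(x, LSTMState.zero(3), p)
    direct = sigmoid(p.w_out @ st.output + p.b_out)
    assert forward(x[None, :], p) == pytest.approx(direct, abs=1e-12)


def test_batched_forward_matches_scalar_forward():
    p = LSTMParams.initialize(4, 2, seed=6)
    x = np.random.default_rng(7).normal(size=(3, 5, 2))
    probs, _ = _forward_batch(x, p)
    for i in range(3):
        assert probs[i] == pytest.approx(forward(x[i], p), abs=1e-12)


@pytest.mark.parametrize("candidate", ["sigmoid", "tanh"])
def test_bptt_gradients_match_finite_differences(candidate):
    """BPTT gradients agree with central finite differences on a tiny net."""
    rng = np.random.default_rng(11)
    b, l, m, h = 3, 2, 2, 3
    x = rng.normal(size=(b, l, m))
    y = np.array([0.0, 1.0, 1.0])
    p = LSTMParams.initialize(h, m, seed=4, candidate_activation=candidate)

    def loss(params):
        probs, _ = _forward_batch(x, params, keep_trace=False)
        eps = 1e-12
        return float(np.mean(
            -y * np.log(probs + eps) - (1 - y) * np.log(1 - probs + eps)
        ))

    probs, pack = _forward_batch(x, p, keep_trace=True)
    grads = _backward_batch(x, y, probs, pack, p)

    eps = 1e-6
    for name in ("W_f", "W_i", "W_o", "W_c", "b_f", "b_c", "w_out"):
        arr = getattr(p, name)
        it = np.nditer(arr, flags=["multi_index"])
        for _ in range(min(arr.size, 4)):
            idx = it.multi_index
            orig = arr[idx]
            arr[idx] = orig + eps
            up = loss(p)
            arr[idx] = orig - eps
            down = loss(p)
            arr[idx] = orig
            numeric = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(numeric, abs=1e-6)
            it.iternext()


# ---------------------------------------------------------------------------
# Training contracts
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=-1.0)


def test_lstm_training_determinism_and_learnability(tiny_easy):
    enc = SequenceEncoding.for_dimension(tiny_easy.n_features, 1)
    cfg = TrainConfig(epochs=50, hidden_size=32, seed=5)
    m1 = train_lstm(tiny_easy, enc, cfg)
    m2 = train_lstm(tiny_easy, enc, cfg)
    for key in m1.params:
        assert np.array_equal(np.asarray(m1.params[key]), np.asarray(m2.params[key]))
    assert max(m1.train_accuracy) >= 0.9
    assert len(m1.train_accuracy) == 50 and len(m1.val_accuracy) == 50


def test_mlp_training_determinism_and_learnability(tiny_easy):
    cfg = TrainConfig(epochs=30, hidden_size=64, seed=5)
    m1 = train_mlp(tiny_easy, cfg)
    m2 = train_mlp(tiny_easy, cfg)
    for key in m1.params:
        assert np.array_equal(np.asarray(m1.params[key]), np.asarray(m2.params[key]))
    assert max(m1.train_accuracy) >= 0.9


def test_training_requires_both_classes(tiny_easy):
    from biruni import FeatureTable

    one_class = FeatureTable(
        values=tiny_easy.values[tiny_easy.labels == 0],
        labels=tiny_easy.labels[tiny_easy.labels == 0],
        feature_ids=tiny_easy.feature_ids,
    )
    with pytest.raises(ValueError):
        train_mlp(one_class, TrainConfig(epochs=1))


def test_model_serialization_round_trip(tmp_path, tiny_easy):
    enc = SequenceEncoding.for_dimension(tiny_easy.n_features, 2)
    model = train_lstm(tiny_easy, enc, TrainConfig(epochs=3, hidden_size=8, seed=1))
    path = tmp_path / "model.json"
    model.to_json(path)
    back = TrainedModel.from_json(path)
    x = tiny_easy.values[:7]
    assert np.allclose(predict_lstm(back, x), predict_lstm(model, x))

    mlp = train_mlp(tiny_easy, TrainConfig(epochs=3, hidden_size=8, seed=1))
    mlp.to_json(path)
    back = TrainedModel.from_json(path)
    assert np.allclose(predict_mlp(back, x), predict_mlp(mlp, x))
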