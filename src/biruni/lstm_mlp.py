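"""LSTM classifier built from the gate equations, plus an MLP baseline.

A flat feature vector of length d is reinterpreted as an ordered sequence of
L steps of m features each (row-major, L*m = d), and a single LSTM cell is
unrolled over it.  The cell follows the gate equations

    f_t  = sigmoid(W_f [y_(t-1), X_t] + b_f)      forget gate
    i_t  = sigmoid(W_i [y_(t-1), X_t] + b_i)      input gate
    O_t  = sigmoid(W_o [y_(t-1), X_t] + b_o)      output gate
    C*_t = act(W_c [y_(t-1), X_t] + b_c)          candidate cell state
    C_t  = C_(t-1) o f_t + C*_t o i_t             memory cell
    y_t  = O_t o tanh(C_t)                        hidden output

with the candidate activation ``act`` defaulting to sigmoid (a tanh variant
is selectable, matching the conventional cell).  Classification is a single
logistic readout on the final y_t, trained with binary cross-entropy by
backpropagation through time (Adam).  The MLP baseline is a one-hidden-layer
feedforward network trained by the same loop, so both models expose the same
per-epoch accuracy traces and determinism contract.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .synthdata import FeatureTable


# ---------------------------------------------------------------------------
# Sequence encoding
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceEncoding:
    """Row-major mapping of a flat d-vector to L timesteps of m features."""

    timesteps: int
    step_dim: int

    def __post_init__(self) -> None:
        if self.timesteps < 1 or self.step_dim < 1:
            raise ValueError("timesteps and step_dim must be >= 1")

    @property
    def feature_dim(self) -> int:
        return self.timesteps * self.step_dim

    @classmethod
    def for_dimension(cls, d: int, step_dim: int = 1) -> "SequenceEncoding":
        if d % step_dim != 0:
            raise ValueError(f"step_dim {step_dim} does not divide dimension {d}")
        return cls(timesteps=d // step_dim, step_dim=step_dim)


def reshape_to_sequence(features: np.ndarray, enc: SequenceEncoding) -> np.ndarray:
    """Split a flat vector into (L, m) preserving order; round-trips exactly."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 1 or features.size != enc.feature_dim:
        raise ValueError(
            f"feature length {features.size} incompatible with "
            f"{enc.timesteps} x {enc.step_dim} encoding"
        )
    return features.reshape(enc.timesteps, enc.step_dim)


# ---------------------------------------------------------------------------
# Cell and forward pass
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


@dataclass
class LSTMParams:
    """Gate weight matrices (H x (H+m)) and biases, plus the logistic readout."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray
    w_out: np.ndarray
    b_out: float
    candidate_activation: str = "sigmoid"

    def __post_init__(self) -> None:
        if self.candidate_activation not in ("sigmoid", "tanh"):
            raise ValueError("candidate_activation must be 'sigmoid' or 'tanh'")
        h, hm = self.W_f.shape
        for w in (self.W_i, self.W_o, self.W_c):
            if w.shape != (h, hm):
                raise ValueError("gate weight matrices must share one shape")
        for b in (self.b_f, self.b_i, self.b_o, self.b_c):
            if b.shape != (h,):
                raise ValueError("gate biases must have length H")
        if self.w_out.shape != (h,):
            raise ValueError("readout weights must have length H")

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def step_dim(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    def _candidate(self, z: np.ndarray) -> np.ndarray:
        return _sigmoid(z) if self.candidate_activation == "sigmoid" else np.tanh(z)

    @classmethod
    def initialize(cls, hidden_size: int, step_dim: int, seed: int,
                   candidate_activation: str = "sigmoid") -> "LSTMParams":
        """Seeded uniform initialization scaled by 1/sqrt(fan-in).

        The forget-gate bias starts at 1 so the memory cell initially
        retains information, which keeps gradients flowing through long
        unrolled sequences (the usual LSTM initialization practice).
        """
        rng = np.random.default_rng(seed)
        fan_in = hidden_size + step_dim
        s = 1.0 / math.sqrt(fan_in)

        def w() -> np.ndarray:
            return rng.uniform(-s, s, size=(hidden_size, fan_in))

        return cls(
            W_f=w(), W_i=w(), W_o=w(), W_c=w(),
            b_f=np.ones(hidden_size), b_i=np.zeros(hidden_size),
            b_o=np.zeros(hidden_size), b_c=np.zeros(hidden_size),
            w_out=rng.uniform(-1, 1, size=hidden_size) / math.sqrt(hidden_size),
            b_out=0.0,
            candidate_activation=candidate_activation,
        )


@dataclass
class LSTMState:
    """Memory cell C_t and hidden output y_t after one cell application."""

    cell: np.ndarray
    output: np.ndarray

    @classmethod
    def zero(cls, hidden_size: int) -> "LSTMState":
        return cls(cell=np.zeros(hidden_size), output=np.zeros(hidden_size))


def lstm_cell(x_t: np.ndarray, prev: LSTMState, params: LSTMParams) -> LSTMState:
    """One application of the gated cell to input x_t given the previous state."""
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.step_dim,):
        raise ValueError(
            f"input length {x_t.shape} does not match step_dim {params.step_dim}"
        )
    a = np.concatenate([prev.output, x_t])
    f = _sigmoid(params.W_f @ a + params.b_f)
    i = _sigmoid(params.W_i @ a + params.b_i)
    o = _sigmoid(params.W_o @ a + params.b_o)
    c_hat = params._candidate(params.W_c @ a + params.b_c)
    c = prev.cell * f + c_hat * i
    y = o * np.tanh(c)
    return LSTMState(cell=c, output=y)


def forward(sequence: np.ndarray, params: LSTMParams) -> float:
    """Unroll the cell from a zero state; logistic readout on the final y_t."""
    sequence = np.asarray(sequence, dtype=float)
    if sequence.ndim != 2 or sequence.shape[0] < 1:
        raise ValueError("sequence must be a nonempty (L, m) array")
    state = LSTMState.zero(params.hidden_size)
    for t in range(sequence.shape[0]):
        state = lstm_cell(sequence[t], state, params)
    logit = float(params.w_out @ state.output + params.b_out)
    return float(_sigmoid(np.array([logit]))[0])


def _forward_batch(x_seq: np.ndarray, params: LSTMParams, keep_trace: bool = False):
    """Vectorized forward over a batch: x_seq is (B, L, m).

    Returns (probabilities, trace); the trace holds per-step intermediates
    needed by backpropagation through time.
    """
    b, l, m = x_seq.shape
    h = params.hidden_size
    y = np.zeros((b, h))
    c = np.zeros((b, h))
    trace = [] if keep_trace else None
    for t in range(l):
        a = np.concatenate([y, x_seq[:, t, :]], axis=1)          # (B, H+m)
        f = _sigmoid(a @ params.W_f.T + params.b_f)
        i = _sigmoid(a @ params.W_i.T + params.b_i)
        o = _sigmoid(a @ params.W_o.T + params.b_o)
        ch = params._candidate(a @ params.W_c.T + params.b_c)
        c_new = c * f + ch * i
        y_new = o * np.tanh(c_new)
        if keep_trace:
            trace.append((a, f, i, o, ch, c, c_new))
        y, c = y_new, c_new
    logits = y @ params.w_out + params.b_out
    probs = _sigmoid(logits)
    return probs, (trace, y)


def _backward_batch(x_seq, y_true, probs, trace_pack, params: LSTMParams):
    """BPTT gradients of mean binary cross-entropy w.r.t. all parameters."""
    trace, y_final = trace_pack
    b, l, m = x_seq.shape
    h = params.hidden_size

    grads = {
        "W_f": np.zeros_like(params.W_f), "W_i": np.zeros_like(params.W_i),
        "W_o": np.zeros_like(params.W_o), "W_c": np.zeros_like(params.W_c),
        "b_f": np.zeros_like(params.b_f), "b_i": np.zeros_like(params.b_i),
        "b_o": np.zeros_like(params.b_o), "b_c": np.zeros_like(params.b_c),
    }
    dlogit = (probs - y_true) / b                                 # (B,)
    grads["w_out"] = y_final.T @ dlogit
    grads["b_out"] = float(dlogit.sum())

    dy = np.outer(dlogit, params.w_out)                           # (B, H)
    dc_carry = np.zeros((b, h))
    for t in range(l - 1, -1, -1):
        a, f, i, o, ch, c_prev, c_new = trace[t]
        tanh_c = np.tanh(c_new)
        do = dy * tanh_c
        dc = dc_carry + dy * o * (1.0 - tanh_c * tanh_c)
        df = dc * c_prev
        di = dc * ch
        dch = dc * i
        dc_carry = dc * f

        dzf = df * f * (1.0 - f)
        dzi = di * i * (1.0 - i)
        dzo = do * o * (1.0 - o)
        if params.candidate_activation == "sigmoid":
            dzc = dch * ch * (1.0 - ch)
        else:
            dzc = dch * (1.0 - ch * ch)

        grads["W_f"] += dzf.T @ a
        grads["W_i"] += dzi.T @ a
        grads["W_o"] += dzo.T @ a
        grads["W_c"] += dzc.T @ a
        grads["b_f"] += dzf.sum(axis=0)
        grads["b_i"] += dzi.sum(axis=0)
        grads["b_o"] += dzo.sum(axis=0)
        grads["b_c"] += dzc.sum(axis=0)

        da = dzf @ params.W_f + dzi @ params.W_i + dzo @ params.W_o + dzc @ params.W_c
        dy = da[:, :h]
    return grads


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Gradient-training settings shared by the LSTM and the MLP baseline."""

    epochs: int = 50
    learning_rate: float = 0.01
    batch_size: int = 32
    hidden_size: int = 32
    seed: int = 0
    candidate_activation: str = "sigmoid"
    val_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1 or self.hidden_size < 1:
            raise ValueError("batch_size and hidden_size must be >= 1")
        if not 0.0 <= self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in [0, 1)")


class _Adam:
    """Plain Adam over a dict of arrays (and scalars)."""

    def __init__(self, lr: float, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, values: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            g = np.asarray(g, dtype=float)
            if k not in self.m:
                self.m[k] = np.zeros_like(g)
                self.v[k] = np.zeros_like(g)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1**self.t)
            vh = self.v[k] / (1 - self.b2**self.t)
            update = self.lr * mh / (np.sqrt(vh) + self.eps)
            if np.isscalar(values[k]) or np.ndim(values[k]) == 0:
                values[k] = float(values[k] - update)
            else:
                values[k] -= update
        return None


def _stratified_split(labels: np.ndarray, val_fraction: float,
                      seed: int) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    train_idx, val_idx = [], []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        n_val = int(round(val_fraction * idx.size))
        val_idx.append(idx[:n_val])
        train_idx.append(idx[n_val:])
    return np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(val_idx))


@dataclass
class TrainedModel:
    """A trained classifier bundle: parameters, scaler, traces, config echo."""

    kind: str                       # "lstm" or "mlp"
    params: dict
    feature_mean: np.ndarray
    feature_std: np.ndarray
    encoding: SequenceEncoding | None
    config: TrainConfig
    train_accuracy: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)

    def lstm_params(self) -> LSTMParams:
        if self.kind != "lstm":
            raise ValueError("not an LSTM model")
        return LSTMParams(
            **{k: self.params[k] for k in
               ("W_f", "W_i", "W_o", "W_c", "b_f", "b_i", "b_o", "b_c", "w_out")},
            b_out=self.params["b_out"],
            candidate_activation=self.config.candidate_activation,
        )

    # --- serialization -----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        def enc(v):
            return v.tolist() if isinstance(v, np.ndarray) else v

        payload = {
            "format_version": 1,
            "kind": self.kind,
            "params": {k: enc(v) for k, v in self.params.items()},
            "feature_mean": self.feature_mean.tolist(),
            "feature_std": self.feature_std.tolist(),
            "encoding": (
                None if self.encoding is None
                else {"timesteps": self.encoding.timesteps,
                      "step_dim": self.encoding.step_dim}
            ),
            "config": self.config.__dict__,
            "train_accuracy": self.train_accuracy,
            "val_accuracy": self.val_accuracy,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text())
        params = {
            k: (np.asarray(v, dtype=float) if isinstance(v, list) else v)
            for k, v in payload["params"].items()
        }
        enc = payload["encoding"]
        return cls(
            kind=payload["kind"],
            params=params,
            feature_mean=np.asarray(payload["feature_mean"], dtype=float),
            feature_std=np.asarray(payload["feature_std"], dtype=float),
            encoding=None if enc is None else SequenceEncoding(**enc),
            config=TrainConfig(**payload["config"]),
            train_accuracy=payload["train_accuracy"],
            val_accuracy=payload["val_accuracy"],
        )


def _standardize_fit(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = x.mean(axis=0)
    std = x.std(axis=0)
    std[std == 0] = 1.0
    return mean, std


def train_lstm(table: FeatureTable, enc: SequenceEncoding,
               cfg: TrainConfig) -> TrainedModel:
    """Train the gated cell + logistic readout by BPTT (Adam, BCE loss).

    Features are standardized on the training portion; a stratified
    ``val_fraction`` split provides the per-epoch validation accuracy trace.
    Identical seed and data give bit-identical parameters.
    """
    if enc.feature_dim != table.n_features:
        raise ValueError("encoding does not match the table's feature dimension")
    if len(np.unique(table.labels)) < 2:
        raise ValueError("training requires both classes present")

    train_idx, val_idx = _stratified_split(table.labels, cfg.val_fraction, cfg.seed)
    mean, std = _standardize_fit(table.values[train_idx])
    x = (table.values - mean) / std
    x_seq = x.reshape(-1, enc.timesteps, enc.step_dim)
    y = table.labels.astype(float)

    params = LSTMParams.initialize(cfg.hidden_size, enc.step_dim, cfg.seed,
                                   cfg.candidate_activation)
    values = {
        "W_f": params.W_f, "W_i": params.W_i, "W_o": params.W_o, "W_c": params.W_c,
        "b_f": params.b_f, "b_i": params.b_i, "b_o": params.b_o, "b_c": params.b_c,
        "w_out": params.w_out, "b_out": params.b_out,
    }
    opt = _Adam(cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    train_acc, val_acc = [], []

    for _ in range(cfg.epochs):
        order = train_idx.copy()
        rng.shuffle(order)
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            params = LSTMParams(**values, candidate_activation=cfg.candidate_activation)
            probs, pack = _forward_batch(x_seq[batch], params, keep_trace=True)
            if not np.all(np.isfinite(probs)):
                raise FloatingPointError("non-finite loss during LSTM training")
            grads = _backward_batch(x_seq[batch], y[batch], probs, pack, params)
            opt.step(values, grads)

        params = LSTMParams(**values, candidate_activation=cfg.candidate_activation)
        p_tr, _ = _forward_batch(x_seq[train_idx], params, keep_trace=False)
        train_acc.append(float(np.mean((p_tr > 0.5) == (y[train_idx] > 0.5))))
        if val_idx.size:
            p_va, _ = _forward_batch(x_seq[val_idx], params, keep_trace=False)
            val_acc.append(float(np.mean((p_va > 0.5) == (y[val_idx] > 0.5))))

    return TrainedModel(
        kind="lstm", params=values, feature_mean=mean, feature_std=std,
        encoding=enc, config=cfg, train_accuracy=train_acc, val_accuracy=val_acc,
    )


def predict_lstm(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Class-1 probabilities for a (n, d) feature matrix."""
    x = (np.atleast_2d(np.asarray(features, dtype=float))
         - model.feature_mean) / model.feature_std
    enc = model.encoding
    x_seq = x.reshape(-1, enc.timesteps, enc.step_dim)
    probs, _ = _forward_batch(x_seq, model.lstm_params(), keep_trace=False)
    return probs


# ---------------------------------------------------------------------------
# MLP baseline
# ---------------------------------------------------------------------------

def _mlp_forward(x, values, keep=False):
    z1 = x @ values["W1"].T + values["b1"]
    h = np.maximum(z1, 0.0)
    logits = h @ values["w_out"] + values["b_out"]
    probs = _sigmoid(logits)
    return (probs, (z1, h)) if keep else (probs, None)


def train_mlp(table: FeatureTable, cfg: TrainConfig | None = None) -> TrainedModel:
    """One-hidden-layer (ReLU) feedforward baseline with a logistic output.

    Consumes the raw flat feature vectors (no sequence reformulation) but
    shares the objective, optimizer, traces and determinism contract of
    :func:`train_lstm`.  Default hidden size is 64.
    """
    if cfg is None:
        cfg = TrainConfig(hidden_size=64)
    if len(np.unique(table.labels)) < 2:
        raise ValueError("training requires both classes present")

    train_idx, val_idx = _stratified_split(table.labels, cfg.val_fraction, cfg.seed)
    mean, std = _standardize_fit(table.values[train_idx])
    x = (table.values - mean) / std
    y = table.labels.astype(float)
    d = table.n_features

    rng0 = np.random.default_rng(cfg.seed)
    values = {
        "W1": rng0.uniform(-1, 1, size=(cfg.hidden_size, d)) / math.sqrt(d),
        "b1": np.zeros(cfg.hidden_size),
        "w_out": rng0.uniform(-1, 1, size=cfg.hidden_size) / math.sqrt(cfg.hidden_size),
        "b_out": 0.0,
    }
    opt = _Adam(cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed + 1)
    train_acc, val_acc = [], []

    for _ in range(cfg.epochs):
        order = train_idx.copy()
        rng.shuffle(order)
        for start in range(0, order.size, cfg.batch_size):
            batch = order[start:start + cfg.batch_size]
            xb, yb = x[batch], y[batch]
            probs, (z1, h) = _mlp_forward(xb, values, keep=True)
            if not np.all(np.isfinite(probs)):
                raise FloatingPointError("non-finite loss during MLP training")
            dlogit = (probs - yb) / xb.shape[0]
            dh = np.outer(dlogit, values["w_out"])
            dz1 = dh * (z1 > 0)
            grads = {
                "W1": dz1.T @ xb, "b1": dz1.sum(axis=0),
                "w_out": h.T @ dlogit, "b_out": float(dlogit.sum()),
            }
            opt.step(values, grads)

        p_tr, _ = _mlp_forward(x[train_idx], values)
        train_acc.append(float(np.mean((p_tr > 0.5) == (y[train_idx] > 0.5))))
        if val_idx.size:
            p_va, _ = _mlp_forward(x[val_idx], values)
            val_acc.append(float(np.mean((p_va > 0.5) == (y[val_idx] > 0.5))))

    return TrainedModel(
        kind="mlp", params=values, feature_mean=mean, feature_std=std,
        encoding=None, config=cfg, train_accuracy=train_acc, val_accuracy=val_acc,
    )


def predict_mlp(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    if model.kind != "mlp":
        raise ValueError("not an MLP model")
    x = (np.atleast_2d(np.asarray(features, dtype=float))
         - model.feature_mean) / model.feature_std
    probs, _ = _mlp_forward(x, model.params)
    return probs


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    """Dispatch on model kind; returns class-1 probabilities."""
    if model.kind == "lstm":
        return predict_lstm(model, features)
    return predict_mlp(model, features)


# ---------------------------------------------------------------------------
# Wrapper-classifier hook for feature selection
# ---------------------------------------------------------------------------

def lstm_cv_error(x: np.ndarray, y: np.ndarray, seed: int = 0,
                  n_folds: int = 5, epochs: int = 15) -> float:
    """k-fold CV misclassification rate of a small LSTM on (x, y).

    Used as the (expensive) LSTM wrapper inside feature-selection fitness;
    the epoch budget is reduced accordingly.
    """
    from sklearn.model_selection import StratifiedKFold

    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    cfg = TrainConfig(epochs=epochs, hidden_size=16, seed=seed, val_fraction=0.0)
    errors = []
    for train_idx, test_idx in splitter.split(x, y):
        sub = FeatureTable(
            values=x[train_idx], labels=y[train_idx],
            feature_ids=[f"f{j}" for j in range(x.shape[1])],
        )
        enc = SequenceEncoding.for_dimension(x.shape[1], step_dim=1)
        model = train_lstm(sub, enc, cfg)
        preds = predict_lstm(model, x[test_idx]) > 0.5
        errors.append(float(np.mean(preds != (y[test_idx] > 0.5))))
    return float(np.mean(errors))
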