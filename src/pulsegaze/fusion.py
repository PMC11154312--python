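"""Fatigue classifiers: two 1D CNNs and a BiLSTM fusion head.

The heart-rate model takes a 1024-sample vector of windowed HRV features,
the face model a 600-sample vector of eye/mouth openness samples; each is
three stride-1 convolutions (HR: 32 filters, kernels 16/8/4; face: 24
filters, kernels 10/5/3) followed by two fully connected layers (HR:
256/128; face: 128/64), dropout, and a 2-way softmax.  No pooling is
inserted between convolutions (the conv stack is flattened directly).

Per-window class probabilities from the two models are concatenated and
fed to a bidirectional LSTM whose per-step forward/backward hidden
states feed a learned softmax head — the "weighted" fusion of the two
modalities.  The LSTM cell follows the gate equations with the output
h_t = gamma_o * C_t (the memory cell passed out through the output gate
without a tanh); ``standard_lstm=True`` restores the conventional
h_t = gamma_o * tanh(C_t).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .nn import Adam, Conv1D, Dense, Dropout, Flatten, ReLU, Sequential, softmax, softmax_cross_entropy

__all__ = [
    "HRModelConfig",
    "FaceModelConfig",
    "CNNClassifier",
    "LSTMCellParams",
    "lstm_step",
    "BiLSTMFusion",
    "TrainResult",
]


@dataclass(frozen=True)
class HRModelConfig:
    input_len: int = 1024
    filters: int = 32
    kernels: tuple[int, int, int] = (16, 8, 4)
    fc_sizes: tuple[int, int] = (256, 128)
    dropout: float = 0.5
    n_classes: int = 2


@dataclass(frozen=True)
class FaceModelConfig:
    input_len: int = 600
    filters: int = 24
    kernels: tuple[int, int, int] = (10, 5, 3)
    fc_sizes: tuple[int, int] = (128, 64)
    dropout: float = 0.5
    n_classes: int = 2


@dataclass
class TrainResult:
    epoch_losses: list[float]
    train_accuracy: float
    epochs_run: int


class CNNClassifier:
    """A configured 1D CNN with standardizing input preprocessing."""

    def __init__(self, cfg: HRModelConfig | FaceModelConfig, seed: int = 0):
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        layers: list = []
        in_ch = 1
        length = cfg.input_len
        for k in cfg.kernels:
            layers += [Conv1D(in_ch, cfg.filters, k, rng), ReLU()]
            in_ch = cfg.filters
            length = length - k + 1
        layers.append(Flatten())
        in_dim = in_ch * length
        for h in cfg.fc_sizes:
            layers += [Dense(in_dim, h, rng), ReLU()]
            in_dim = h
        layers.append(Dropout(cfg.dropout))
        layers.append(Dense(in_dim, cfg.n_classes, rng))
        self.net = Sequential(layers)
        # input standardization fitted on the training set
        self.x_mean = np.zeros(cfg.input_len)
        self.x_std = np.ones(cfg.input_len)

    def _prep(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.cfg.input_len:
            raise ValueError(f"input length {X.shape[1]} != {self.cfg.input_len}")
        return ((X - self.x_mean) / self.x_std)[:, None, :]  # (B, 1, L)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class probabilities, deterministic (dropout off)."""
        return softmax(self.net.forward(self._prep(X), train=False))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def fit(
        self,
        X: np.ndarray,
        y: np.ndarray,
        epochs: int = 50,
        batch_size: int = 32,
        lr: float = 1e-3,
        seed: int = 0,
        early_stop_loss: float = 1e-3,
    ) -> TrainResult:
        """Adam + cross-entropy training, deterministic given the seed.

        Stops early once the epoch loss falls below ``early_stop_loss``
        (the classes the models see are well separated, so convergence
        is quick).
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.x_mean = X.mean(axis=0)
        self.x_std = X.std(axis=0)
        self.x_std[self.x_std < 1e-9] = 1.0
        rng = np.random.default_rng(seed)
        opt = Adam(self.net.parameters(), lr=lr)
        n = X.shape[0]
        losses: list[float] = []
        for epoch in range(epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                xb = self._prep(X[idx])
                logits = self.net.forward(xb, train=True, rng=rng)
                loss, dlogits = softmax_cross_entropy(logits, y[idx])
                self.net.backward(dlogits)
                opt.step()
                epoch_loss += loss * idx.size
            losses.append(epoch_loss / n)
            if losses[-1] < early_stop_loss:
                break
        acc = float(np.mean(self.predict(X) == y))
        return TrainResult(epoch_losses=losses, train_accuracy=acc, epochs_run=len(losses))

    # -- checkpointing --------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {"x_mean": self.x_mean, "x_std": self.x_std}
        for i, layer in enumerate(self.net.layers):
            for name, val in layer.params.items():
                arrays[f"layer{i}_{name}"] = val
        header = json.dumps({"config": self.cfg.__dict__, "kind": type(self.cfg).__name__},
                            default=list, sort_keys=True)
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str) -> "CNNClassifier":
        data = np.load(path)
        header = json.loads(bytes(data["__header__"]).decode())
        cfg_cls = {"HRModelConfig": HRModelConfig, "FaceModelConfig": FaceModelConfig}[header["kind"]]
        raw = {k: tuple(v) if isinstance(v, list) else v for k, v in header["config"].items()}
        model = cls(cfg_cls(**raw))
        model.x_mean = data["x_mean"]
        model.x_std = data["x_std"]
        for i, layer in enumerate(model.net.layers):
            for name in layer.params:
                layer.params[name] = data[f"layer{i}_{name}"]
        return model


# --- LSTM ---------------------------------------------------------------


@dataclass
class LSTMCellParams:
    """Gate weights acting on the concatenated [h_prev, x_t] vector."""

    W_f: np.ndarray
    W_u: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_u: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def hidden(self) -> int:
        return self.W_f.shape[0]

    @classmethod
    def init(cls, input_dim: int, hidden: int, rng: np.random.Generator) -> "LSTMCellParams":
        d = input_dim + hidden
        scale = 1.0 / np.sqrt(d)

        def w():
            return rng.normal(0.0, scale, size=(hidden, d))

        return cls(
            W_f=w(), W_u=w(), W_c=w(), W_o=w(),
            b_f=np.ones(hidden),  # forget bias 1: remember by default
            b_u=np.zeros(hidden), b_c=np.zeros(hidden), b_o=np.zeros(hidden),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def lstm_step(
    params: LSTMCellParams,
    x_t: np.ndarray,
    h_prev: np.ndarray,
    c_prev: np.ndarray,
    standard_lstm: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update on (batch, dim) arrays.

    gamma_f/u/o = sigma(W [h_prev, x] + b); C~ = tanh(W_c [h_prev, x] + b_c);
    C_t = gamma_u * C~ + gamma_f * C_prev; h_t = gamma_o * C_t (or
    gamma_o * tanh(C_t) when ``standard_lstm``).
    """
    x_t = np.atleast_2d(np.asarray(x_t, dtype=float))
    h_prev = np.atleast_2d(np.asarray(h_prev, dtype=float))
    c_prev = np.atleast_2d(np.asarray(c_prev, dtype=float))
    z = np.concatenate([h_prev, x_t], axis=1)
    if z.shape[1] != params.W_f.shape[1]:
        raise ValueError(
            f"[h, x] width {z.shape[1]} does not match weights ({params.W_f.shape[1]})"
        )
    gf = _sigmoid(z @ params.W_f.T + params.b_f)
    gu = _sigmoid(z @ params.W_u.T + params.b_u)
    go = _sigmoid(z @ params.W_o.T + params.b_o)
    c_tilde = np.tanh(z @ params.W_c.T + params.b_c)
    c_t = gu * c_tilde + gf * c_prev
    h_t = go * (np.tanh(c_t) if standard_lstm else c_t)
    return h_t, c_t


class _LSTMDirection:
    """One direction of the BiLSTM with cached forward pass for BPTT."""

    def __init__(self, input_dim: int, hidden: int, rng: np.random.Generator, standard_lstm: bool):
        self.p = LSTMCellParams.init(input_dim, hidden, rng)
        self.standard = standard_lstm
        self.grads = {k: np.zeros_like(getattr(self.p, k)) for k in
                      ("W_f", "W_u", "W_c", "W_o", "b_f", "b_u", "b_c", "b_o")}

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, D) -> hidden states (B, T, H); caches intermediates."""
        B, T, _ = x.shape
        H = self.p.hidden
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self.cache = []
        out = np.zeros((B, T, H))
        for t in range(T):
            z = np.concatenate([h, x[:, t]], axis=1)
            gf = _sigmoid(z @ self.p.W_f.T + self.p.b_f)
            gu = _sigmoid(z @ self.p.W_u.T + self.p.b_u)
            go = _sigmoid(z @ self.p.W_o.T + self.p.b_o)
            ct = np.tanh(z @ self.p.W_c.T + self.p.b_c)
            c_new = gu * ct + gf * c
            a = np.tanh(c_new) if self.standard else c_new
            h_new = go * a
            self.cache.append((z, gf, gu, go, ct, c, c_new, a))
            h, c = h_new, c_new
            out[:, t] = h
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """dout: (B, T, H) grads on hidden states -> (B, T, D) input grads."""
        B, T, H = dout.shape
        D = self.cache[0][0].shape[1] - H
        dx = np.zeros((B, T, D))
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for name in self.grads:
            self.grads[name][...] = 0.0
        for t in reversed(range(T)):
            z, gf, gu, go, ct, c_prev, c_new, a = self.cache[t]
            dh = dout[:, t] + dh_next
            dgo = dh * a
            dc = dc_next.copy()
            if self.standard:
                dc += dh * go * (1.0 - a * a)
            else:
                dc += dh * go
            dgu = dc * ct
            dct = dc * gu
            dgf = dc * c_prev
            dc_next = dc * gf
            dzf = dgf * gf * (1 - gf)
            dzu = dgu * gu * (1 - gu)
            dzo = dgo * go * (1 - go)
            dzc = dct * (1 - ct * ct)
            self.grads["W_f"] += dzf.T @ z
            self.grads["W_u"] += dzu.T @ z
            self.grads["W_o"] += dzo.T @ z
            self.grads["W_c"] += dzc.T @ z
            self.grads["b_f"] += dzf.sum(axis=0)
            self.grads["b_u"] += dzu.sum(axis=0)
            self.grads["b_o"] += dzo.sum(axis=0)
            self.grads["b_c"] += dzc.sum(axis=0)
            dz = dzf @ self.p.W_f + dzu @ self.p.W_u + dzo @ self.p.W_o + dzc @ self.p.W_c
            dh_next = dz[:, :H]
            dx[:, t] = dz[:, H:]
        return dx


class BiLSTMFusion:
    """Bidirectional LSTM over per-window modality probabilities.

    Input: sequences (B, T, D) of concatenated [hr_probs, face_probs]
    per window.  Output: a per-window fatigue probability from a softmax
    head on the concatenated forward/backward hidden states.
    """

    def __init__(self, input_dim: int = 4, hidden: int = 8, seed: int = 0,
                 standard_lstm: bool = False):
        rng = np.random.default_rng(seed)
        self.fwd = _LSTMDirection(input_dim, hidden, rng, standard_lstm)
        self.bwd = _LSTMDirection(input_dim, hidden, rng, standard_lstm)
        self.head = Dense(2 * hidden, 2, rng)
        self.hidden = hidden
        self.input_dim = input_dim
        self.standard_lstm = standard_lstm

    def _hidden_states(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)  # (B, T, 2H)

    def predict_proba(self, sequences: np.ndarray) -> np.ndarray:
        """(B, T, D) -> per-window class probabilities (B, T, 2)."""
        x = np.asarray(sequences, dtype=float)
        if x.ndim == 2:
            x = x[None]
        if x.shape[2] != self.input_dim:
            raise ValueError(f"sequence feature dim {x.shape[2]} != {self.input_dim}")
        hcat = self._hidden_states(x)
        B, T, H2 = hcat.shape
        logits = self.head.forward(hcat.reshape(B * T, H2))
        return softmax(logits).reshape(B, T, 2)

    def predict(self, sequences: np.ndarray) -> np.ndarray:
        return self.predict_proba(sequences).argmax(axis=2)

    def fit(
        self,
        sequences: np.ndarray,
        labels: np.ndarray,
        epochs: int = 50,
        lr: float = 0.02,
        seed: int = 0,
        early_stop_loss: float = 1e-3,
    ) -> TrainResult:
        """Full-batch BPTT with Adam; labels are per window (B, T)."""
        x = np.asarray(sequences, dtype=float)
        y = np.asarray(labels, dtype=int)
        if x.shape[:2] != y.shape:
            raise ValueError("misaligned sequences and labels")
        B, T, _ = x.shape
        handles = []
        for direction in (self.fwd, self.bwd):
            for name in direction.grads:
                handles.append(_DirHandle(direction, name))
        handles_pairs = [(h, "p") for h in handles] + [(self.head, n) for n in self.head.params]
        opt = Adam(handles_pairs, lr=lr)
        losses = []
        for _ in range(epochs):
            hcat = self._hidden_states(x)
            logits = self.head.forward(hcat.reshape(B * T, -1))
            loss, dlogits = softmax_cross_entropy(logits, y.reshape(-1))
            dh = self.head.backward(dlogits).reshape(B, T, -1)
            H = self.hidden
            self.fwd.backward(dh[:, :, :H])
            self.bwd.backward(dh[:, ::-1, H:])
            opt.step()
            losses.append(loss)
            if loss < early_stop_loss:
                break
        acc = float(np.mean(self.predict(x) == y))
        return TrainResult(epoch_losses=losses, train_accuracy=acc, epochs_run=len(losses))

    def direction_swapped(self) -> "BiLSTMFusion":
        """Model with forward/backward roles exchanged (head blocks too).

        Structurally, running the swapped model on the time-reversed
        sequence and reversing its output reproduces this model's
        predictions exactly.
        """
        import copy

        other = copy.deepcopy(self)
        other.fwd, other.bwd = other.bwd, other.fwd
        W = other.head.params["W"]
        H = self.hidden
        other.head.params["W"] = np.concatenate([W[H:], W[:H]], axis=0)
        return other

    # -- checkpointing --------------------------------------------------
    def save(self, path: str) -> None:
        arrays = {}
        for tag, d in (("fwd", self.fwd), ("bwd", self.bwd)):
            for name in d.grads:
                arrays[f"{tag}_{name}"] = getattr(d.p, name)
        arrays["head_W"] = self.head.params["W"]
        arrays["head_b"] = self.head.params["b"]
        meta = {"input_dim": self.input_dim, "hidden": self.hidden,
                "standard_lstm": self.standard_lstm}
        arrays["__header__"] = np.frombuffer(json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "BiLSTMFusion":
        data = np.load(path)
        meta = json.loads(bytes(data["__header__"]).decode())
        model = cls(**meta)
        for tag, d in (("fwd", model.fwd), ("bwd", model.bwd)):
            for name in d.grads:
                setattr(d.p, name, data[f"{tag}_{name}"])
        model.head.params["W"] = data["head_W"]
        model.head.params["b"] = data["head_b"]
        return model


class _DirHandle:
    """Exposes one LSTM-direction parameter through the Adam layer API."""

    def __init__(self, direction: _LSTMDirection, name: str):
        self._d = direction
        self._name = name

    @property
    def params(self):
        return {"p": getattr(self._d.p, self._name)}

    def __setattr__(self, key, value):
        object.__setattr__(self, key, value)

    @property
    def grads(self):
        return {"p": self._d.grads[self._name]}
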