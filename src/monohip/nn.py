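"""Recurrent neural networks in NumPy for per-cycle hip ROM prediction.

Implements the small sequence models used for hip ROM regression and
3-class classification from 100 x 7 gait-cycle tensors: simple RNN, GRU and
LSTM cells, a bidirectional first recurrent layer, dropout after every
recurrent and hidden layer, dense heads, and Adam optimization of the mean
squared error (regression) or softmax cross-entropy (classification).

Backpropagation through time is written out by hand; the analytic gradients
are verified against central finite differences in the test suite. The
models are deliberately small (tens of units, hundreds of cycles) and run
on a single CPU core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CELLS = ("simple", "gru", "lstm")


@dataclass
class RNNSpec:
    """Architecture description for a recurrent ROM predictor."""

    cell: str = "gru"
    units: int = 16
    dropout_rate: float = 0.2
    learning_rate: float = 1e-3
    task: str = "regression"        # or "classification"
    n_classes: int = 3
    seq_len: int = 100
    n_channels: int = 7

    def __post_init__(self) -> None:
        if self.cell not in CELLS:
            raise ValueError(f"unknown cell type {self.cell!r}; "
                             f"expected one of {CELLS}")
        if self.units < 1:
            raise ValueError("units must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.task not in ("regression", "classification"):
            raise ValueError("task must be 'regression' or 'classification'")

    @property
    def activation(self) -> str:
        # tanh hidden/recurrent activations for regression, ReLU for
        # classification
        return "tanh" if self.task == "regression" else "relu"


# ---------------------------------------------------------------------------
# primitives
# ---------------------------------------------------------------------------

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _act(name: str, x: np.ndarray) -> np.ndarray:
    return np.tanh(x) if name == "tanh" else np.maximum(x, 0.0)


def _act_grad(name: str, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Derivative of the activation given pre-activation x and output y."""
    return 1.0 - y * y if name == "tanh" else (x > 0).astype(x.dtype)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int
            ) -> np.ndarray:
    lim = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


class _Layer:
    """Interface: params/grads are parallel lists of arrays."""

    params: list[np.ndarray]
    grads: list[np.ndarray]

    def forward(self, x: np.ndarray, training: bool,
                rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int,
                 activation: str = "linear"):
        self.W = _glorot(rng, n_in, n_out)
        self.b = np.zeros(n_out)
        self.activation = activation
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, training, rng):
        self._x = x
        self._a = x @ self.W + self.b
        if self.activation == "linear":
            self._y = self._a
        else:
            self._y = _act(self.activation, self._a)
        return self._y

    def backward(self, dy):
        if self.activation != "linear":
            dy = dy * _act_grad(self.activation, self._a, self._y)
        self.grads[0] += self._x.T @ dy
        self.grads[1] += dy.sum(axis=0)
        return dy @ self.W.T


class Dropout(_Layer):
    def __init__(self, rate: float):
        self.rate = rate
        self.params = []
        self.grads = []

    def forward(self, x, training, rng):
        if not training or self.rate <= 0.0:
            self._mask = None
            return x
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


# ---------------------------------------------------------------------------
# recurrent cells (batch-major input: (B, T, C))
# ---------------------------------------------------------------------------

class _RecurrentBase(_Layer):
    def __init__(self, return_sequences: bool, go_backwards: bool):
        self.return_sequences = return_sequences
        self.go_backwards = go_backwards

    def _maybe_reverse(self, x: np.ndarray) -> np.ndarray:
        return x[:, ::-1] if self.go_backwards else x

    def forward(self, x, training, rng):
        x = self._maybe_reverse(np.asarray(x))
        y = self._forward_seq(x)
        if self.return_sequences:
            return y[:, ::-1] if self.go_backwards else y
        return y

    def backward(self, dy):
        if self.return_sequences and self.go_backwards:
            dy = dy[:, ::-1]
        dx = self._backward_seq(dy)
        return dx[:, ::-1] if self.go_backwards else dx


class SimpleRNN(_RecurrentBase):
    def __init__(self, rng, n_in, units, activation="tanh",
                 return_sequences=False, go_backwards=False):
        super().__init__(return_sequences, go_backwards)
        self.units = units
        self.activation = activation
        self.Wx = _glorot(rng, n_in, units)
        self.Wh = _glorot(rng, units, units)
        self.b = np.zeros(units)
        self.params = [self.Wx, self.Wh, self.b]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _forward_seq(self, x):
        B, T, _ = x.shape
        h = np.zeros((B, self.units))
        A = np.empty((B, T, self.units))
        H = np.empty((B, T, self.units))
        for t in range(T):
            A[:, t] = x[:, t] @ self.Wx + h @ self.Wh + self.b
            h = _act(self.activation, A[:, t])
            H[:, t] = h
        self._x, self._A, self._H = x, A, H
        return H if self.return_sequences else h

    def _backward_seq(self, dy):
        x, A, H = self._x, self._A, self._H
        B, T, _ = x.shape
        dWx, dWh, db = self.grads
        dx = np.zeros_like(x)
        carry = np.zeros((B, self.units))
        for t in range(T - 1, -1, -1):
            dh = carry + (dy[:, t] if self.return_sequences
                          else (dy if t == T - 1 else 0.0))
            da = dh * _act_grad(self.activation, A[:, t], H[:, t])
            h_prev = H[:, t - 1] if t > 0 else np.zeros((B, self.units))
            dWx += x[:, t].T @ da
            dWh += h_prev.T @ da
            db += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.T
            carry = da @ self.Wh.T
        return dx


class GRU(_RecurrentBase):
    def __init__(self, rng, n_in, units, activation="tanh",
                 return_sequences=False, go_backwards=False):
        super().__init__(return_sequences, go_backwards)
        self.units = units
        self.activation = activation
        self.Wz, self.Wr, self.Wc = (_glorot(rng, n_in, units)
                                     for _ in range(3))
        self.Uz, self.Ur, self.Uc = (_glorot(rng, units, units)
                                     for _ in range(3))
        self.bz, self.br, self.bc = (np.zeros(units) for _ in range(3))
        self.params = [self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br,
                       self.Wc, self.Uc, self.bc]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _forward_seq(self, x):
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        cache = []
        H = np.empty((B, T, U))
        for t in range(T):
            xt = x[:, t]
            z = _sigmoid(xt @ self.Wz + h @ self.Uz + self.bz)
            r = _sigmoid(xt @ self.Wr + h @ self.Ur + self.br)
            a_c = xt @ self.Wc + (r * h) @ self.Uc + self.bc
            c = _act(self.activation, a_c)
            h_new = z * h + (1.0 - z) * c
            cache.append((xt, h, z, r, a_c, c))
            h = h_new
            H[:, t] = h
        self._cache, self._x_shape = cache, x.shape
        return H if self.return_sequences else h

    def _backward_seq(self, dy):
        B, T, _ = self._x_shape
        (dWz, dUz, dbz, dWr, dUr, dbr, dWc, dUc, dbc) = self.grads
        dx = np.zeros(self._x_shape)
        carry = np.zeros((B, self.units))
        for t in range(T - 1, -1, -1):
            xt, h_prev, z, r, a_c, c = self._cache[t]
            dh = carry + (dy[:, t] if self.return_sequences
                          else (dy if t == T - 1 else 0.0))
            dz = dh * (h_prev - c)
            dc = dh * (1.0 - z)
            dh_prev = dh * z
            da_c = dc * _act_grad(self.activation, a_c, c)
            dWc += xt.T @ da_c
            dUc += (r * h_prev).T @ da_c
            dbc += da_c.sum(axis=0)
            drh = da_c @ self.Uc.T
            dr = drh * h_prev
            dh_prev += drh * r
            da_z = dz * z * (1.0 - z)
            da_r = dr * r * (1.0 - r)
            dWz += xt.T @ da_z
            dUz += h_prev.T @ da_z
            dbz += da_z.sum(axis=0)
            dWr += xt.T @ da_r
            dUr += h_prev.T @ da_r
            dbr += da_r.sum(axis=0)
            dh_prev += da_z @ self.Uz.T + da_r @ self.Ur.T
            dx[:, t] = da_c @ self.Wc.T + da_z @ self.Wz.T + da_r @ self.Wr.T
            carry = dh_prev
        return dx


class LSTM(_RecurrentBase):
    def __init__(self, rng, n_in, units, activation="tanh",
                 return_sequences=False, go_backwards=False):
        super().__init__(return_sequences, go_backwards)
        self.units = units
        self.activation = activation
        self.Wi, self.Wf, self.Wo, self.Wg = (_glorot(rng, n_in, units)
                                              for _ in range(4))
        self.Ui, self.Uf, self.Uo, self.Ug = (_glorot(rng, units, units)
                                              for _ in range(4))
        self.bi, self.bo, self.bg = (np.zeros(units) for _ in range(3))
        self.bf = np.ones(units)  # forget-gate bias init at 1
        self.params = [self.Wi, self.Ui, self.bi, self.Wf, self.Uf, self.bf,
                       self.Wo, self.Uo, self.bo, self.Wg, self.Ug, self.bg]
        self.grads = [np.zeros_like(p) for p in self.params]

    def _forward_seq(self, x):
        B, T, _ = x.shape
        U = self.units
        h = np.zeros((B, U))
        c = np.zeros((B, U))
        cache = []
        H = np.empty((B, T, U))
        for t in range(T):
            xt = x[:, t]
            i = _sigmoid(xt @ self.Wi + h @ self.Ui + self.bi)
            f = _sigmoid(xt @ self.Wf + h @ self.Uf + self.bf)
            o = _sigmoid(xt @ self.Wo + h @ self.Uo + self.bo)
            a_g = xt @ self.Wg + h @ self.Ug + self.bg
            g = _act(self.activation, a_g)
            c_new = f * c + i * g
            hc = _act(self.activation, c_new)
            h_new = o * hc
            cache.append((xt, h, c, i, f, o, a_g, g, c_new, hc))
            h, c = h_new, c_new
            H[:, t] = h
        self._cache, self._x_shape = cache, x.shape
        return H if self.return_sequences else h

    def _backward_seq(self, dy):
        B, T, _ = self._x_shape
        (dWi, dUi, dbi, dWf, dUf, dbf, dWo, dUo, dbo,
         dWg, dUg, dbg) = self.grads
        dx = np.zeros(self._x_shape)
        carry_h = np.zeros((B, self.units))
        carry_c = np.zeros((B, self.units))
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, o, a_g, g, c, hc = self._cache[t]
            dh = carry_h + (dy[:, t] if self.return_sequences
                            else (dy if t == T - 1 else 0.0))
            do = dh * hc
            dc = dh * o * _act_grad(self.activation, c, hc) + carry_c
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            carry_c = dc * f
            da_i = di * i * (1.0 - i)
            da_f = df * f * (1.0 - f)
            da_o = do * o * (1.0 - o)
            da_g = dg * _act_grad(self.activation, a_g, g)
            for (dW, dU, db, da) in ((dWi, dUi, dbi, da_i),
                                     (dWf, dUf, dbf, da_f),
                                     (dWo, dUo, dbo, da_o),
                                     (dWg, dUg, dbg, da_g)):
                dW += xt.T @ da
                dU += h_prev.T @ da
                db += da.sum(axis=0)
            carry_h = (da_i @ self.Ui.T + da_f @ self.Uf.T
                       + da_o @ self.Uo.T + da_g @ self.Ug.T)
            dx[:, t] = (da_i @ self.Wi.T + da_f @ self.Wf.T
                        + da_o @ self.Wo.T + da_g @ self.Wg.T)
        return dx


_CELL_CLASSES = {"simple": SimpleRNN, "gru": GRU, "lstm": LSTM}


class Bidirectional(_Layer):
    """Runs a forward and a time-reversed copy of a cell and concatenates
    their outputs along the feature axis."""

    def __init__(self, rng, cell: str, n_in: int, units: int,
                 activation: str, return_sequences: bool = True):
        cls = _CELL_CLASSES[cell]
        self.fwd = cls(rng, n_in, units, activation, return_sequences, False)
        self.bwd = cls(rng, n_in, units, activation, return_sequences, True)
        self.params = self.fwd.params + self.bwd.params
        self.grads = self.fwd.grads + self.bwd.grads

    def forward(self, x, training, rng):
        yf = self.fwd.forward(x, training, rng)
        yb = self.bwd.forward(x, training, rng)
        self._split = yf.shape[-1]
        return np.concatenate([yf, yb], axis=-1)

    def backward(self, dy):
        k = self._split
        return self.fwd.backward(dy[..., :k]) + self.bwd.backward(
            dy[..., k:])


# ---------------------------------------------------------------------------
# network
# ---------------------------------------------------------------------------

def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)


class RecurrentNet:
    """Sequence model: bidirectional recurrent layer, second recurrent
    layer, two dense hidden layers (dropout after each of the four), and a
    linear (regression) or softmax (classification) output."""

    def __init__(self, spec: RNNSpec, seed: int = 17):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        act = spec.activation
        U = spec.units
        out_dim = 1 if spec.task == "regression" else spec.n_classes
        self.layers: list[_Layer] = [
            Bidirectional(rng, spec.cell, spec.n_channels, U, act,
                          return_sequences=True),
            Dropout(spec.dropout_rate),
            _CELL_CLASSES[spec.cell](rng, 2 * U, U, act,
                                     return_sequences=False),
            Dropout(spec.dropout_rate),
            Dense(rng, U, U, act),
            Dropout(spec.dropout_rate),
            Dense(rng, U, U, act),
            Dropout(spec.dropout_rate),
            Dense(rng, U, out_dim, "linear"),
        ]
        self.history = TrainingHistory()
        self._rng = rng
        params = [p for lyr in self.layers for p in lyr.params]
        self._m = [np.zeros_like(p) for p in params]
        self._v = [np.zeros_like(p) for p in params]
        self._step = 0

    # -- forward / loss ----------------------------------------------------

    def _check_input(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.spec.seq_len \
                or X.shape[2] != self.spec.n_channels:
            raise ValueError(
                f"expected input of shape (n, {self.spec.seq_len}, "
                f"{self.spec.n_channels}), got {X.shape}")
        return X

    def _forward(self, X: np.ndarray, training: bool) -> np.ndarray:
        out = X
        for lyr in self.layers:
            out = lyr.forward(out, training, self._rng)
        return out

    def _loss_grad(self, out: np.ndarray, y: np.ndarray
                   ) -> tuple[float, np.ndarray]:
        n = len(y)
        if self.spec.task == "regression":
            resid = out[:, 0] - y
            loss = float(np.mean(resid ** 2))
            dout = np.zeros_like(out)
            dout[:, 0] = 2.0 * resid / n
            return loss, dout
        p = _softmax(out)
        idx = y.astype(int)
        loss = float(-np.mean(np.log(p[np.arange(n), idx] + 1e-12)))
        dout = p.copy()
        dout[np.arange(n), idx] -= 1.0
        return loss, dout / n

    def loss_and_grads(self, X: np.ndarray, y: np.ndarray
                       ) -> tuple[float, list[np.ndarray]]:
        """One full forward/backward pass (no dropout); exposed for
        gradient verification."""
        X = self._check_input(X)
        for lyr in self.layers:
            for g in lyr.grads:
                g[...] = 0.0
        out = self._forward(X, training=False)
        loss, dout = self._loss_grad(out, np.asarray(y))
        for lyr in reversed(self.layers):
            dout = lyr.backward(dout)
        return loss, [g.copy() for lyr in self.layers for g in lyr.grads]

    # -- training ----------------------------------------------------------

    def _adam_step(self) -> None:
        lr = self.spec.learning_rate
        b1, b2, eps = 0.9, 0.999, 1e-8
        self._step += 1
        t = self._step
        params = [p for lyr in self.layers for p in lyr.params]
        grads = [g for lyr in self.layers for g in lyr.grads]
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** t)
            vhat = v / (1 - b2 ** t)
            p -= lr * mhat / (np.sqrt(vhat) + eps)

    def fit(self, X: np.ndarray, y: np.ndarray, epochs: int = 30,
            batch_size: int = 32) -> "RecurrentNet":
        X = self._check_input(X)
        y = np.asarray(y, dtype=float)
        n = len(X)
        for _ in range(epochs):
            order = self._rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, batch_size):
                sel = order[start:start + batch_size]
                for lyr in self.layers:
                    for g in lyr.grads:
                        g[...] = 0.0
                out = self._forward(X[sel], training=True)
                loss, dout = self._loss_grad(out, y[sel])
                for lyr in reversed(self.layers):
                    dout = lyr.backward(dout)
                self._adam_step()
                epoch_loss += loss * len(sel)
            self.history.loss.append(epoch_loss / n)
        return self

    # -- inference ---------------------------------------------------------

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predicted ROM (regression) or class labels 1..K
        (classification)."""
        X = self._check_input(X)
        out = self._forward(X, training=False)
        if self.spec.task == "regression":
            return out[:, 0]
        return np.argmax(_softmax(out), axis=1) + 1

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        if self.spec.task != "classification":
            raise ValueError("predict_proba requires a classification spec")
        X = self._check_input(X)
        return _softmax(self._forward(X, training=False))


def build_rnn(spec: RNNSpec, seed: int = 17) -> RecurrentNet:
    """Construct the recurrent predictor for a given architecture spec."""
    return RecurrentNet(spec, seed=seed)
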