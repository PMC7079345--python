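"""Minimal NumPy neural-network engine for the DTI classifiers.

Implements exactly what the classifiers need — stacked LSTM layers, dense
layers, inverted dropout, a 2-way softmax head trained with mean-squared
error, and the Nadam optimizer — with hand-derived backpropagation.
Gradient correctness is pinned by finite-difference tests.

Conventions: sequence tensors are (batch, time, features); gate order in the
packed LSTM weight matrices is input, forget, cell, output; dropout uses the
inverted (expectation-scaling) convention, so inference needs no rescaling
and is equivalent in expectation to the halved-weight "mean network".
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def mse_loss_and_grad(p: np.ndarray, y_onehot: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error between softmax outputs and one-hot labels.

    Returns the loss and its gradient with respect to the pre-softmax
    logits (the softmax Jacobian is folded in).
    """
    diff = p - y_onehot
    loss = float(np.mean(diff**2))
    dp = 2.0 * diff / diff.size
    # backprop through softmax: dz = p * (dp - sum(dp * p))
    dz = p * (dp - np.sum(dp * p, axis=1, keepdims=True))
    return loss, dz


class LSTMLayer:
    """One LSTM layer over a (batch, time, d_in) sequence.

    Logistic-sigmoid input/forget/output gates, tanh cell input and output
    activations, zero initial state.  Packed weights: Wx (d_in, 4u),
    Wh (u, 4u), b (4u,), giving 4(d_in*u + u^2 + u) parameters.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator, init_sd: float = 0.1):
        if units < 1:
            raise ValueError("units must be >= 1")
        self.d_in, self.units = d_in, units
        self.Wx = rng.normal(0.0, init_sd, size=(d_in, 4 * units))
        self.Wh = rng.normal(0.0, init_sd, size=(units, 4 * units))
        self.b = rng.normal(0.0, init_sd, size=4 * units)

    @property
    def n_parameters(self) -> int:
        return 4 * (self.d_in * self.units + self.units**2 + self.units)

    def params(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        B, T, _ = x.shape
        u = self.units
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        self._cache = []
        out = np.empty((B, T, u))
        for t in range(T):
            xt = x[:, t, :]
            z = xt @ self.Wx + h @ self.Wh + self.b
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            self._cache.append((xt, i, f, g, o, c_prev, c, tc, h))
            h = o * tc
            out[:, t, :] = h
        self._x_shape = x.shape
        self._out = out
        return out

    def backward(self, dout: np.ndarray):
        B, T, _ = self._x_shape
        u = self.units
        dWx = np.zeros_like(self.Wx)
        dWh = np.zeros_like(self.Wh)
        db = np.zeros_like(self.b)
        dx = np.empty(self._x_shape)
        dh_carry = np.zeros((B, u))
        dc_carry = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            xt, i, f, g, o, c_prev, c, tc, h_prev = self._cache[t]
            dh = dout[:, t, :] + dh_carry
            do = dh * tc
            dc = dh * o * (1.0 - tc**2) + dc_carry
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_carry = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g**2),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dWx += xt.T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t, :] = dz @ self.Wx.T
            dh_carry = dz @ self.Wh.T
        self._grads = [dWx, dWh, db]
        return dx

    def grads(self):
        return self._grads


class DenseLayer:
    """Fully connected layer with optional tanh activation on 2-D input."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 activation: str | None = None, init_sd: float | None = 0.1):
        if init_sd is None:  # Glorot: preserves activation variance in depth
            init_sd = np.sqrt(2.0 / (d_in + d_out))
            self.b = np.zeros(d_out)
        else:
            self.b = rng.normal(0.0, init_sd, size=d_out)
        self.W = rng.normal(0.0, init_sd, size=(d_in, d_out))
        self.activation = activation

    @property
    def n_parameters(self) -> int:
        return self.W.size + self.b.size

    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        z = x @ self.W + self.b
        if self.activation == "tanh":
            self._a = np.tanh(z)
            return self._a
        return z

    def backward(self, dout: np.ndarray):
        if self.activation == "tanh":
            dout = dout * (1.0 - self._a**2)
        self._grads = [self._x.T @ dout, dout.sum(axis=0)]
        return dout @ self.W.T

    def grads(self):
        return self._grads


class Dropout:
    """Inverted dropout; identity at inference (mean-network equivalent)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng = rng

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dout: np.ndarray):
        if self._mask is None:
            return dout
        return dout * self._mask


class LastStep:
    """Select the final timestep: (B, T, u) -> (B, u)."""

    def params(self):
        return []

    def grads(self):
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dout: np.ndarray):
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dout
        return dx


class Network:
    """A plain layer stack ending in 2-way logits (softmax applied outside)."""

    def __init__(self, layers: list):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def get_weights(self):
        return [p.copy() for p in self.params()]

    def set_weights(self, weights) -> None:
        for p, w in zip(self.params(), weights, strict=True):
            p[...] = w

    @property
    def n_parameters(self) -> int:
        return sum(p.size for p in self.params())


class Nadam:
    """Nesterov-accelerated Adam with a 1/(1 + decay*epoch) learning rate.

    beta1 plays the role of the momentum coefficient; beta2 and epsilon are
    the usual second-moment defaults.
    """

    def __init__(self, params: list[np.ndarray], learning_rate: float = 0.002,
                 lr_decay: float = 0.004, momentum: float = 0.5,
                 beta2: float = 0.999, epsilon: float = 1e-8):
        self.params = params
        self.lr0 = learning_rate
        self.decay = lr_decay
        self.beta1 = momentum
        self.beta2 = beta2
        self.eps = epsilon
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0
        self.epoch = 0

    @property
    def current_lr(self) -> float:
        return self.lr0 / (1.0 + self.decay * self.epoch)

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        lr = self.current_lr
        for p, g, m, v in zip(self.params, grads, self.m, self.v, strict=True):
            m[...] = b1 * m + (1.0 - b1) * g
            v[...] = b2 * v + (1.0 - b2) * g**2
            m_hat = m / bc1
            v_hat = v / bc2
            # Nesterov look-ahead on the first moment
            update = (b1 * m_hat + (1.0 - b1) * g / bc1) / (np.sqrt(v_hat) + self.eps)
            p -= lr * update
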