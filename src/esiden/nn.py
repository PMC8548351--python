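"""Minimal numpy neural-network primitives for recurrent sequence regression.

Implements exactly what the torsion-angle network needs: an LSTM layer
with masked backpropagation-through-time over padded batches, dense
layers, inverted dropout, and the Adam optimizer.  All forward passes
cache what the analytic backward pass needs; gradients are verified
against finite differences in the test suite.

Masking contract: inputs are (B, T, C) with a boolean mask (B, T); at
masked (padding) steps the recurrent state is carried through unchanged,
so per-position outputs at valid steps are independent of the amount of
trailing padding.
"""

from __future__ import annotations

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class LSTMLayer:
    """Single-direction LSTM with gate order (input, forget, cell, output).

    Parameters: W (I, 4H) input weights, U (H, 4H) recurrent weights,
    b (4H,) bias with the forget-gate slice initialised to 1.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 name: str = "lstm"):
        self.I, self.H, self.name = input_size, hidden_size, name
        s = 1.0 / np.sqrt(hidden_size)
        self.W = rng.uniform(-s, s, size=(input_size, 4 * hidden_size))
        self.U = rng.uniform(-s, s, size=(hidden_size, 4 * hidden_size))
        self.b = np.zeros(4 * hidden_size)
        self.b[hidden_size:2 * hidden_size] = 1.0  # forget-gate bias
        self.zero_grads()

    def parameters(self):
        return [(f"{self.name}.W", "W"), (f"{self.name}.U", "U"),
                (f"{self.name}.b", "b")]

    def n_params(self) -> int:
        return self.W.size + self.U.size + self.b.size

    def zero_grads(self):
        self.dW = np.zeros_like(self.W)
        self.dU = np.zeros_like(self.U)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """x: (B, T, I); mask: (B, T) float or bool. Returns (B, T, H)."""
        B, T, _ = x.shape
        H = self.H
        m = mask.astype(float)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        self._cache = {"x": x, "m": m, "i": [], "f": [], "g": [], "o": [],
                       "c_cand": [], "h_prev": [], "c_prev": []}
        hs = np.empty((B, T, H))
        cs_i, cs_f, cs_g, cs_o = self._cache["i"], self._cache["f"], \
            self._cache["g"], self._cache["o"]
        for t in range(T):
            self._cache["h_prev"].append(h)
            self._cache["c_prev"].append(c)
            z = x[:, t] @ self.W + h @ self.U + self.b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = sigmoid(z[:, 3 * H:])
            c_cand = f * c + i * g
            h_cand = o * np.tanh(c_cand)
            mt = m[:, t][:, None]
            c = mt * c_cand + (1 - mt) * c
            h = mt * h_cand + (1 - mt) * h
            cs_i.append(i); cs_f.append(f); cs_g.append(g); cs_o.append(o)
            self._cache["c_cand"].append(c_cand)
            hs[:, t] = h
        return hs

    def backward(self, dh_seq: np.ndarray) -> np.ndarray:
        """dh_seq: (B, T, H) gradient w.r.t. outputs. Returns dx (B, T, I)."""
        cache = self._cache
        x, m = cache["x"], cache["m"]
        B, T, _ = x.shape
        H = self.H
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H))
        dc_next = np.zeros((B, H))
        for t in range(T - 1, -1, -1):
            i, f, g, o = (cache[k][t] for k in ("i", "f", "g", "o"))
            c_cand = cache["c_cand"][t]
            h_prev, c_prev = cache["h_prev"][t], cache["c_prev"][t]
            mt = m[:, t][:, None]
            dh = dh_seq[:, t] + dh_next
            dc = dc_next
            # masked steps pass state (and its gradient) straight through
            dh_cand = dh * mt
            dh_pass = dh * (1 - mt)
            tanh_c = np.tanh(c_cand)
            do = dh_cand * tanh_c
            dc_cand = dc * mt + dh_cand * o * (1 - tanh_c ** 2)
            dc_pass = dc * (1 - mt)
            di = dc_cand * g
            df = dc_cand * c_prev
            dg = dc_cand * i
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            self.dW += x[:, t].T @ dz
            self.dU += h_prev.T @ dz
            self.db += dz.sum(axis=0)
            dx[:, t] = dz @ self.W.T
            dh_next = dz @ self.U.T + dh_pass
            dc_next = dc_cand * f + dc_pass
        return dx


class BiLSTMLayer:
    """Forward + backward LSTM over the valid region; outputs concatenated.

    The backward direction is run by flipping sequences in time together
    with their masks (padding becomes leading and is skipped by the mask
    logic), so trailing padding never reaches the reversed recurrence.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 name: str = "bilstm"):
        self.fwd = LSTMLayer(input_size, hidden_size, rng, name=f"{name}.fwd")
        self.bwd = LSTMLayer(input_size, hidden_size, rng, name=f"{name}.bwd")
        self.H = hidden_size

    def n_params(self) -> int:
        return self.fwd.n_params() + self.bwd.n_params()

    def zero_grads(self):
        self.fwd.zero_grads()
        self.bwd.zero_grads()

    def forward(self, x: np.ndarray, mask: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x, mask)
        hb = self.bwd.forward(x[:, ::-1], mask[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=2)

    def backward(self, dh_seq: np.ndarray) -> np.ndarray:
        H = self.H
        dxf = self.fwd.backward(dh_seq[:, :, :H])
        dxb = self.bwd.backward(dh_seq[:, ::-1, H:])[:, ::-1]
        return dxf + dxb


class DenseLayer:
    """Per-position affine map with optional ReLU."""

    def __init__(self, input_size: int, output_size: int, rng: np.random.Generator,
                 relu: bool = False, name: str = "fc"):
        s = np.sqrt(2.0 / input_size) if relu else np.sqrt(1.0 / input_size)
        self.W = rng.normal(0.0, s, size=(input_size, output_size))
        self.b = np.zeros(output_size)
        self.relu = relu
        self.name = name
        self.zero_grads()

    def n_params(self) -> int:
        return self.W.size + self.b.size

    def zero_grads(self):
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        y = x @ self.W + self.b
        if self.relu:
            self._pre = y
            y = np.maximum(y, 0.0)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.relu:
            dy = dy * (self._pre > 0)
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.dW += x2.T @ dy2
        self.db += dy2.sum(axis=0)
        return dy @ self.W.T


class Dropout:
    """Inverted dropout; active only when a generator is supplied."""

    def __init__(self, p: float):
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x: np.ndarray, rng: np.random.Generator | None) -> np.ndarray:
        if rng is None or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Adam:
    """Adam over a flat list of (param_array, grad_getter) pairs."""

    def __init__(self, params_and_grads, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.pg = params_and_grads  # list of (owner, param_attr, grad_attr)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(getattr(o, p)) for o, p, _ in self.pg]
        self.v = [np.zeros_like(getattr(o, p)) for o, p, _ in self.pg]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, (owner, p_attr, g_attr) in enumerate(self.pg):
            g = getattr(owner, g_attr)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            param = getattr(owner, p_attr)
            param -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def masked_mse(pred: np.ndarray, target: np.ndarray, mask: np.ndarray):
    """Mean squared error over unmasked entries; returns (loss, dpred).

    Masked entries contribute exactly zero loss and zero gradient.
    """
    w = mask.astype(float)
    n = w.sum()
    if n == 0:
        raise ValueError("no unmasked target entries")
    diff = (pred - target) * w
    loss = float((diff ** 2).sum() / n)
    dpred = 2.0 * diff / n
    return loss, dpred
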