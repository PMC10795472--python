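"""Minimal NumPy building blocks for the sequence networks.

Implements exactly what the event classifier needs — an LSTM over padded,
masked variable-length sequences returning the final recurrent state, a
feed-forward stack, and an Adam optimizer with global-norm gradient clipping.
Forward and backward passes are hand-derived; everything runs in float32 on a
single CPU and is fully determined by the seeding Generator.
"""

from __future__ import annotations

import numpy as np

__all__ = ["LSTM", "MLP", "Adam", "softmax", "sigmoid", "global_norm_clip"]


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class LSTM:
    """Single-layer LSTM consuming (B, T, I) inputs with a (B, T) mask.

    ``cell_activation`` controls the candidate/output non-linearity: the
    classifier and assessor use ``"identity"`` (an LSTM without activation
    function on the state readout); ``"tanh"`` gives the textbook variant.
    Masked steps freeze the state, so the returned final hidden state is that
    of the last valid step and is invariant to trailing padding.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 cell_activation: str = "identity"):
        if cell_activation not in ("identity", "tanh"):
            raise ValueError(f"unknown cell_activation {cell_activation!r}")
        self.I, self.H = input_size, hidden_size
        self.cell_activation = cell_activation
        k = 1.0 / np.sqrt(hidden_size)
        self.params = {
            "Wx": rng.uniform(-k, k, (input_size, 4 * hidden_size)).astype(np.float32),
            "Wh": rng.uniform(-k, k, (hidden_size, 4 * hidden_size)).astype(np.float32),
            "b": np.zeros(4 * hidden_size, dtype=np.float32),
        }
        self.params["b"][hidden_size : 2 * hidden_size] = 1.0  # forget-gate bias
        self.grads = {k_: np.zeros_like(v) for k_, v in self.params.items()}
        self._cache = None

    def _act(self, x):
        return np.tanh(x) if self.cell_activation == "tanh" else x

    def forward(self, X: np.ndarray, mask: np.ndarray, cache: bool = True) -> np.ndarray:
        B, T, _ = X.shape
        H = self.H
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        h = np.zeros((B, H), dtype=np.float32)
        c = np.zeros((B, H), dtype=np.float32)
        steps = []
        for t in range(T):
            x_t = X[:, t, :]
            m = mask[:, t][:, None].astype(np.float32)
            z = x_t @ Wx + h @ Wh + b
            i = sigmoid(z[:, :H])
            f = sigmoid(z[:, H : 2 * H])
            g = self._act(z[:, 2 * H : 3 * H])
            o = sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            hc = self._act(c_new)
            h_new = o * hc
            if cache:
                steps.append((x_t, h, c, i, f, g, o, c_new, hc, m, z[:, 2 * H : 3 * H]))
            h = m * h_new + (1.0 - m) * h
            c = m * c_new + (1.0 - m) * c
        if cache:
            self._cache = steps
        return h

    def backward(self, dh: np.ndarray) -> None:
        """Backprop from the gradient of the loss w.r.t. the final hidden state."""
        steps = self._cache
        if steps is None:
            raise RuntimeError("forward(cache=True) must run before backward")
        gWx, gWh, gb = self.grads["Wx"], self.grads["Wh"], self.grads["b"]
        Wh = self.params["Wh"]
        dh = dh.astype(np.float32)
        dc = np.zeros_like(dh)
        for x_t, h_prev, c_prev, i, f, g, o, c_new, hc, m, zg in reversed(steps):
            dh_t = dh * m
            dh_skip = dh * (1.0 - m)
            dc_t = dc * m
            dc_skip = dc * (1.0 - m)
            do = dh_t * hc
            dhc = dh_t * o
            if self.cell_activation == "tanh":
                dc_new = dc_t + dhc * (1.0 - hc * hc)
            else:
                dc_new = dc_t + dhc
            di = dc_new * g
            df = dc_new * c_prev
            dg = dc_new * i
            dc_prev = dc_new * f
            if self.cell_activation == "tanh":
                dzg = dg * (1.0 - g * g)
            else:
                dzg = dg
            dz = np.concatenate(
                [di * i * (1.0 - i), df * f * (1.0 - f), dzg, do * o * (1.0 - o)], axis=1
            )
            gWx += x_t.T @ dz
            gWh += h_prev.T @ dz
            gb += dz.sum(axis=0)
            dh = dz @ Wh.T + dh_skip
            dc = dc_prev + dc_skip
        self._cache = None


class MLP:
    """Feed-forward stack; hidden activation relu or tanh, linear final layer."""

    def __init__(self, sizes: list[int], activation: str, rng: np.random.Generator):
        if activation not in ("relu", "tanh"):
            raise ValueError(f"unknown activation {activation!r}")
        self.activation = activation
        self.params = {}
        for layer, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = np.sqrt(2.0 / n_in) if activation == "relu" else np.sqrt(1.0 / n_in)
            self.params[f"W{layer}"] = (rng.standard_normal((n_in, n_out)) * scale).astype(
                np.float32
            )
            self.params[f"b{layer}"] = np.zeros(n_out, dtype=np.float32)
        self.n_layers = len(sizes) - 1
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        self._cache = None

    def forward(self, x: np.ndarray, cache: bool = True) -> np.ndarray:
        acts = [x.astype(np.float32)]
        pre = []
        for layer in range(self.n_layers):
            z = acts[-1] @ self.params[f"W{layer}"] + self.params[f"b{layer}"]
            pre.append(z)
            if layer < self.n_layers - 1:
                a = np.maximum(z, 0.0) if self.activation == "relu" else np.tanh(z)
            else:
                a = z
            acts.append(a)
        if cache:
            self._cache = (acts, pre)
        return acts[-1]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        acts, pre = self._cache
        d = dout.astype(np.float32)
        for layer in range(self.n_layers - 1, -1, -1):
            if layer < self.n_layers - 1:
                if self.activation == "relu":
                    d = d * (pre[layer] > 0)
                else:
                    a = acts[layer + 1]
                    d = d * (1.0 - a * a)
            self.grads[f"W{layer}"] += acts[layer].T @ d
            self.grads[f"b{layer}"] += d.sum(axis=0)
            d = d @ self.params[f"W{layer}"].T
        self._cache = None
        return d


def global_norm_clip(modules, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = 0.0
    for mod in modules:
        for g in mod.grads.values():
            total += float(np.sum(g.astype(np.float64) ** 2))
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        scale = np.float32(max_norm / norm)
        for mod in modules:
            for g in mod.grads.values():
                g *= scale
    return float(norm)


class Adam:
    """Adaptive-moment optimizer over the parameters of several modules."""

    def __init__(self, modules, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.modules = list(modules)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [
            {k: np.zeros_like(v) for k, v in mod.params.items()} for mod in self.modules
        ]
        self.v = [
            {k: np.zeros_like(v) for k, v in mod.params.items()} for mod in self.modules
        ]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for mod, m_s, v_s in zip(self.modules, self.m, self.v):
            for key, p in mod.params.items():
                g = mod.grads[key]
                m_s[key] = b1 * m_s[key] + (1 - b1) * g
                v_s[key] = b2 * v_s[key] + (1 - b2) * g * g
                p -= (
                    self.lr * (m_s[key] / bias1) / (np.sqrt(v_s[key] / bias2) + self.eps)
                ).astype(np.float32)
                g.fill(0.0)
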