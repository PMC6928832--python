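"""Minimal gated recurrent layer with exact backprop-through-time.

Standard GRU update (sigmoid gates, tanh candidate):

    z_t = sigma(x_t Wz + h_{t-1} Uz + bz)        update gate
    r_t = sigma(x_t Wr + h_{t-1} Ur + br)        reset gate
    c_t = tanh(x_t Wh + (r_t * h_{t-1}) Uh + bh) candidate state
    h_t = (1 - z_t) * h_{t-1} + z_t * c_t

All arithmetic is float64; gradients are exact (verified against central
finite differences in the test suite).
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))


class GRULayer:
    """One GRU layer over full sequences, shape convention (batch, time, dim)."""

    PARAM_NAMES = ("Wz", "Uz", "bz", "Wr", "Ur", "br", "Wh", "Uh", "bh")

    def __init__(self, input_dim: int, hidden_dim: int, rng: np.random.Generator):
        self.input_dim = input_dim
        self.hidden_dim = hidden_dim

        def glorot(fan_in: int, fan_out: int) -> np.ndarray:
            s = np.sqrt(6.0 / (fan_in + fan_out))
            return rng.uniform(-s, s, size=(fan_in, fan_out))

        for gate in "zrh":
            setattr(self, f"W{gate}", glorot(input_dim, hidden_dim))
            setattr(self, f"U{gate}", glorot(hidden_dim, hidden_dim))
            setattr(self, f"b{gate}", np.zeros(hidden_dim))

    def params(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.PARAM_NAMES}

    def forward(self, x_seq: np.ndarray, h0: np.ndarray):
        """Run the layer; returns (h_seq, cache) with h_seq (B, T, H)."""
        B, T, _ = x_seq.shape
        H = self.hidden_dim
        hs = np.empty((B, T, H))
        zs = np.empty((B, T, H))
        rs = np.empty((B, T, H))
        cs = np.empty((B, T, H))
        h = h0
        for t in range(T):
            x = x_seq[:, t]
            z = _sigmoid(x @ self.Wz + h @ self.Uz + self.bz)
            r = _sigmoid(x @ self.Wr + h @ self.Ur + self.br)
            c = np.tanh(x @ self.Wh + (r * h) @ self.Uh + self.bh)
            h = (1.0 - z) * h + z * c
            hs[:, t], zs[:, t], rs[:, t], cs[:, t] = h, z, r, c
        return hs, (x_seq, h0, hs, zs, rs, cs)

    def backward(self, cache, dh_seq: np.ndarray | None = None,
                 dh_last: np.ndarray | None = None):
        """BPTT.  ``dh_seq`` is the gradient flowing into every hidden state
        (e.g. from a per-step readout); ``dh_last`` an extra gradient into
        the final state.  Returns (param grads, dx_seq, dh0)."""
        x_seq, h0, hs, zs, rs, cs = cache
        B, T, _ = x_seq.shape
        grads = {name: np.zeros_like(p) for name, p in self.params().items()}
        dx_seq = np.zeros_like(x_seq)
        dh = np.zeros((B, self.hidden_dim)) if dh_last is None else dh_last.copy()
        for t in range(T - 1, -1, -1):
            if dh_seq is not None:
                dh = dh + dh_seq[:, t]
            h_prev = h0 if t == 0 else hs[:, t - 1]
            z, r, c = zs[:, t], rs[:, t], cs[:, t]
            x = x_seq[:, t]

            dc = dh * z
            dz = dh * (c - h_prev)
            dh_prev = dh * (1.0 - z)

            da_c = dc * (1.0 - c * c)
            grads["Wh"] += x.T @ da_c
            grads["Uh"] += (r * h_prev).T @ da_c
            grads["bh"] += da_c.sum(axis=0)
            drh = da_c @ self.Uh.T
            dr = drh * h_prev
            dh_prev += drh * r

            da_r = dr * r * (1.0 - r)
            grads["Wr"] += x.T @ da_r
            grads["Ur"] += h_prev.T @ da_r
            grads["br"] += da_r.sum(axis=0)
            dh_prev += da_r @ self.Ur.T

            da_z = dz * z * (1.0 - z)
            grads["Wz"] += x.T @ da_z
            grads["Uz"] += h_prev.T @ da_z
            grads["bz"] += da_z.sum(axis=0)
            dh_prev += da_z @ self.Uz.T

            dx_seq[:, t] = da_c @ self.Wh.T + da_r @ self.Wr.T + da_z @ self.Wz.T
            dh = dh_prev
        return grads, dx_seq, dh


class Adam:
    """Adam optimiser over a flat dict of parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in params.items():
            g = grads[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1 ** self.t)
            v_hat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
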