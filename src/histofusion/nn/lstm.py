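"""Peephole LSTM implemented in NumPy with full backpropagation through time.

The recurrence, for input x_t, hidden h_{t-1} and cell c_{t-1}:

    i_t = sigma(W_xi x_t + W_hi h_{t-1} + w_ci * c_{t-1} + b_i)
    f_t = sigma(W_xf x_t + W_hf h_{t-1} + w_cf * c_{t-1} + b_f)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    o_t = sigma(W_xo x_t + W_ho h_{t-1} + w_co * c_t + b_o)
    h_t = o_t * tanh(c_t)

The peephole weights (w_ci, w_cf, w_co) act elementwise on the cell state,
i.e. they are diagonal connections.  ``lstm_step`` is the pure functional
single-step form; ``PeepholeLSTM`` adds trainable parameters, batched
masked-sequence forward, and BPTT.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .layers import Param


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))


@dataclass
class LSTMState:
    """Hidden/cell state plus the gate activations that produced it."""

    h: np.ndarray
    c: np.ndarray
    i: np.ndarray | None = None
    f: np.ndarray | None = None
    o: np.ndarray | None = None


def init_lstm_params(input_dim: int, hidden_dim: int,
                     rng: np.random.Generator,
                     scale: float | None = None) -> dict[str, np.ndarray]:
    """Random parameter dict; peephole weights are vectors (diagonal)."""
    s = scale if scale is not None else 1.0 / np.sqrt(hidden_dim)
    p = {}
    for gate in ("i", "f", "c", "o"):
        p[f"W_x{gate}"] = rng.normal(0, s, size=(input_dim, hidden_dim))
        p[f"W_h{gate}"] = rng.normal(0, s, size=(hidden_dim, hidden_dim))
        p[f"b_{gate}"] = np.zeros(hidden_dim)
    for gate in ("i", "f", "o"):
        p[f"w_c{gate}"] = rng.normal(0, s, size=hidden_dim)
    return p


def zero_state(hidden_dim: int, batch: int = 1) -> LSTMState:
    return LSTMState(h=np.zeros((batch, hidden_dim)),
                     c=np.zeros((batch, hidden_dim)))


def lstm_step(x_t: np.ndarray, prev: LSTMState,
              params: dict[str, np.ndarray]) -> LSTMState:
    """One peephole-LSTM step on a batch (rows of ``x_t``)."""
    x_t = np.atleast_2d(x_t)
    h, c = np.atleast_2d(prev.h), np.atleast_2d(prev.c)
    if x_t.shape[1] != params["W_xi"].shape[0]:
        raise ValueError(
            f"input dim {x_t.shape[1]} != expected {params['W_xi'].shape[0]}")
    if h.shape[1] != params["W_hi"].shape[0]:
        raise ValueError("hidden state dim mismatch")
    i = sigmoid(x_t @ params["W_xi"] + h @ params["W_hi"]
                + c * params["w_ci"] + params["b_i"])
    f = sigmoid(x_t @ params["W_xf"] + h @ params["W_hf"]
                + c * params["w_cf"] + params["b_f"])
    g = np.tanh(x_t @ params["W_xc"] + h @ params["W_hc"] + params["b_c"])
    c_new = f * c + i * g
    o = sigmoid(x_t @ params["W_xo"] + h @ params["W_ho"]
                + c_new * params["w_co"] + params["b_o"])
    h_new = o * np.tanh(c_new)
    return LSTMState(h=h_new, c=c_new, i=i, f=f, o=o)


class PeepholeLSTM:
    """Trainable peephole LSTM over masked sequences."""

    def __init__(self, input_dim: int, hidden_dim: int,
                 rng: np.random.Generator):
        self.input_dim, self.hidden_dim = input_dim, hidden_dim
        self.p = {k: Param(v)
                  for k, v in init_lstm_params(input_dim, hidden_dim,
                                               rng).items()}
        self._cache = None

    def _np_params(self) -> dict[str, np.ndarray]:
        return {k: v.value for k, v in self.p.items()}

    def forward(self, X: np.ndarray, mask: np.ndarray | None = None
                ) -> np.ndarray:
        """Run the recurrence over X of shape (B, T, D).

        ``mask`` (B, T) marks valid steps; at a masked (padded) step the
        state passes through unchanged and the output is zero.  Returns the
        hidden outputs H of shape (B, T, hidden).
        """
        B, T, D = X.shape
        if mask is None:
            mask = np.ones((B, T))
        params = self._np_params()
        h = np.zeros((B, self.hidden_dim))
        c = np.zeros((B, self.hidden_dim))
        H = np.zeros((B, T, self.hidden_dim))
        steps = []
        for t in range(T):
            m = mask[:, t][:, None]
            st = lstm_step(X[:, t], LSTMState(h=h, c=c), params)
            g = np.tanh(X[:, t] @ params["W_xc"] + h @ params["W_hc"]
                        + params["b_c"])
            steps.append({"x": X[:, t], "h_prev": h, "c_prev": c,
                          "i": st.i, "f": st.f, "o": st.o, "g": g,
                          "c": st.c, "m": m})
            h = m * st.h + (1 - m) * h
            c = m * st.c + (1 - m) * c
            H[:, t] = m * st.h
        self._cache = steps
        return H

    def backward(self, dH: np.ndarray) -> np.ndarray:
        """BPTT given gradients w.r.t. the masked hidden outputs."""
        steps = self._cache
        B, T, _ = dH.shape
        params = self._np_params()
        grads = {k: np.zeros_like(v) for k, v in params.items()}
        dX = np.zeros((B, T, self.input_dim))
        dh_carry = np.zeros((B, self.hidden_dim))
        dc_carry = np.zeros((B, self.hidden_dim))
        for t in reversed(range(T)):
            s = steps[t]
            m = s["m"]
            # total grad on this step's (masked) new state
            dh_new = m * (dH[:, t] + dh_carry)
            dc_new_carry = m * dc_carry
            # passthrough to the previous state where masked
            dh_prev = (1 - m) * dh_carry
            dc_prev = (1 - m) * dc_carry

            tanh_c = np.tanh(s["c"])
            do = dh_new * tanh_c
            da_o = do * s["o"] * (1 - s["o"])
            dc = dh_new * s["o"] * (1 - tanh_c ** 2) + dc_new_carry \
                + da_o * params["w_co"]
            di = dc * s["g"]
            da_i = di * s["i"] * (1 - s["i"])
            df = dc * s["c_prev"]
            da_f = df * s["f"] * (1 - s["f"])
            dg = dc * s["i"]
            da_g = dg * (1 - s["g"] ** 2)

            dc_prev += dc * s["f"] + da_i * params["w_ci"] \
                + da_f * params["w_cf"]
            dh_prev += da_i @ params["W_hi"].T + da_f @ params["W_hf"].T \
                + da_g @ params["W_hc"].T + da_o @ params["W_ho"].T
            dX[:, t] = da_i @ params["W_xi"].T + da_f @ params["W_xf"].T \
                + da_g @ params["W_xc"].T + da_o @ params["W_xo"].T

            x, hp, cp = s["x"], s["h_prev"], s["c_prev"]
            grads["W_xi"] += x.T @ da_i
            grads["W_xf"] += x.T @ da_f
            grads["W_xc"] += x.T @ da_g
            grads["W_xo"] += x.T @ da_o
            grads["W_hi"] += hp.T @ da_i
            grads["W_hf"] += hp.T @ da_f
            grads["W_hc"] += hp.T @ da_g
            grads["W_ho"] += hp.T @ da_o
            grads["b_i"] += da_i.sum(axis=0)
            grads["b_f"] += da_f.sum(axis=0)
            grads["b_c"] += da_g.sum(axis=0)
            grads["b_o"] += da_o.sum(axis=0)
            grads["w_ci"] += (da_i * cp).sum(axis=0)
            grads["w_cf"] += (da_f * cp).sum(axis=0)
            grads["w_co"] += (da_o * s["c"]).sum(axis=0)

            dh_carry, dc_carry = dh_prev, dc_prev
        for k, g in grads.items():
            self.p[k].grad += g
        return dX

    def params(self):
        return list(self.p.values())
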