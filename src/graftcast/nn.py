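"""Minimal GRU encoder-decoder sequence model, implemented in NumPy.

The forecaster maps a z-scored eGFR input sequence to a predicted output
sequence: a GRU encoder consumes the input days and its final hidden state
seeds a GRU decoder that emits one value per future day, feeding each
prediction back as the next decoder input (teacher forcing optionally
substitutes the true value during training). Forward and backward passes
(truncated BPTT over the full window) and the Adam optimizer are written
directly against NumPy arrays, which keeps the model dependency-free,
CPU-friendly at the sizes involved (hidden state of a few dozen units,
windows of 5-90 days), and bit-reproducible under a fixed seed.

Gradients are stopped at the autoregressive feedback path (the fed-back
prediction is treated as a constant input), a standard simplification that
keeps backpropagation per-step local and training stable.

The decoder's output layer emits a *deviation from the last observed input
value* rather than an absolute level: the prediction at step t is
``last_input + offset_t``. With near-zero initial weights the untrained
model therefore reproduces the persistence forecast (last value carried
forward) and training only has to learn departures from it — a residual
parameterization that stabilizes learning on series that are flat over
long stretches, as post-recovery eGFR is.
"""

from __future__ import annotations

import numpy as np

__all__ = ["GRUSeq2Seq", "AdamState"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class GRUSeq2Seq:
    """Encoder-decoder GRU with scalar inputs/outputs.

    Parameters are held in a flat dict of arrays (gate order r, z, n),
    making optimizer updates, serialization and digesting straightforward.
    """

    PARAM_KEYS = (
        "enc_W", "enc_U", "enc_b",
        "dec_W", "dec_U", "dec_b",
        "out_W", "out_b",
    )

    def __init__(self, hidden_size: int, rng: np.random.Generator):
        if hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        self.hidden_size = H = hidden_size
        s = 1.0 / np.sqrt(H)
        u = lambda shape: rng.uniform(-s, s, size=shape)
        self.params: dict[str, np.ndarray] = {
            "enc_W": u((1, 3 * H)),
            "enc_U": u((H, 3 * H)),
            "enc_b": np.zeros(3 * H),
            "dec_W": u((1, 3 * H)),
            "dec_U": u((H, 3 * H)),
            "dec_b": np.zeros(3 * H),
            "out_W": u((H, 1)),
            "out_b": np.zeros(1),
        }

    # -- single GRU step -----------------------------------------------------

    def _cell_forward(self, prefix: str, x: np.ndarray, h: np.ndarray):
        """One GRU step for a (B, 1) input and (B, H) state; returns (h', cache)."""
        H = self.hidden_size
        p = self.params
        gx = x @ p[f"{prefix}_W"] + p[f"{prefix}_b"]
        gh = h @ p[f"{prefix}_U"]
        r = _sigmoid(gx[:, :H] + gh[:, :H])
        z = _sigmoid(gx[:, H : 2 * H] + gh[:, H : 2 * H])
        n = np.tanh(gx[:, 2 * H :] + r * gh[:, 2 * H :])
        h_new = (1.0 - z) * n + z * h
        return h_new, (x, h, r, z, n, gh)

    def _cell_backward(self, prefix: str, dh_new: np.ndarray, cache, grads):
        """Backprop one GRU step; returns gradient w.r.t. the previous state."""
        H = self.hidden_size
        p = self.params
        x, h, r, z, n, gh = cache
        dn = dh_new * (1.0 - z)
        dz = dh_new * (h - n)
        dh = dh_new * z

        da_n = dn * (1.0 - n * n)
        dr = da_n * gh[:, 2 * H :]
        da_r = dr * r * (1.0 - r)
        da_z = dz * z * (1.0 - z)

        dgx = np.concatenate([da_r, da_z, da_n], axis=1)
        dgh = np.concatenate([da_r, da_z, da_n * r], axis=1)

        grads[f"{prefix}_W"] += x.T @ dgx
        grads[f"{prefix}_b"] += dgx.sum(axis=0)
        grads[f"{prefix}_U"] += h.T @ dgh
        dh += dgh @ p[f"{prefix}_U"].T
        return dh

    # -- full sequence -------------------------------------------------------

    def forward(
        self,
        inputs: np.ndarray,
        output_len: int,
        targets: np.ndarray | None = None,
        teacher_mask: np.ndarray | None = None,
    ):
        """Run encoder + autoregressive decoder.

        Parameters
        ----------
        inputs : (B, T_in) z-scored values.
        output_len : number of decoder steps.
        targets : (B, T_out), required when ``teacher_mask`` is given.
        teacher_mask : (T_out,) booleans; True steps feed the true value
            back instead of the prediction (training-time teacher forcing).

        Returns ``(predictions (B, T_out), cache)``.
        """
        B, T_in = inputs.shape
        H = self.hidden_size
        h = np.zeros((B, H))
        enc_caches = []
        for t in range(T_in):
            h, cache = self._cell_forward("enc", inputs[:, t : t + 1], h)
            enc_caches.append(cache)

        preds = np.empty((B, output_len))
        dec_caches = []
        base = inputs[:, -1:]  # persistence baseline: last observed input
        x = base
        p = self.params
        for t in range(output_len):
            h, cache = self._cell_forward("dec", x, h)
            y = base + h @ p["out_W"] + p["out_b"]  # residual on the baseline
            preds[:, t] = y[:, 0]
            dec_caches.append((cache, h))
            if teacher_mask is not None and teacher_mask[t]:
                x = targets[:, t : t + 1]
            else:
                x = y  # fed back as a constant (gradient stopped)
        return preds, (enc_caches, dec_caches, B)

    def backward(self, dpreds: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Backpropagate a (B, T_out) gradient on the predictions."""
        enc_caches, dec_caches, B = cache
        p = self.params
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        dh = np.zeros((B, self.hidden_size))
        for t in range(len(dec_caches) - 1, -1, -1):
            step_cache, h_t = dec_caches[t]
            dy = dpreds[:, t : t + 1]
            grads["out_W"] += h_t.T @ dy
            grads["out_b"] += dy.sum(axis=0)
            dh = dh + dy @ p["out_W"].T
            dh = self._cell_backward("dec", dh, step_cache, grads)
        for t in range(len(enc_caches) - 1, -1, -1):
            dh = self._cell_backward("enc", dh, enc_caches[t], grads)
        return grads

    # -- persistence ---------------------------------------------------------

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k in self.PARAM_KEYS:
            self.params[k] = np.asarray(weights[k], dtype=float).copy()
        self.hidden_size = self.params["enc_U"].shape[0]

    def weights_digest(self) -> str:
        import hashlib

        hasher = hashlib.sha256()
        for k in self.PARAM_KEYS:
            hasher.update(k.encode())
            hasher.update(np.ascontiguousarray(self.params[k]).tobytes())
        return hasher.hexdigest()


class AdamState:
    """Adam optimizer over a parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            m_hat = self.m[k] / (1 - b1**self.t)
            v_hat = self.v[k] / (1 - b2**self.t)
            params[k] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
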