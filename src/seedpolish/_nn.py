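"""Minimal NumPy recurrent network used by the error-pattern classifier.

Two GRU encoders (one over the seed-structure tensor S, one over the
context tensor X), final hidden states concatenated into a linear
softmax head.  Forward, backprop-through-time, and a decoupled
weight-decay Adam (AdamW) optimizer are implemented directly on NumPy
arrays; sequences within a batch share a common length.
"""

from __future__ import annotations

import numpy as np


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class GRUEncoder:
    """Single-layer GRU; returns the final hidden state.

    Gate layout inside the fused weight matrices is [update z | reset r
    | candidate c], each a block of ``hidden`` columns.
    """

    def __init__(self, n_in: int, hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(hidden)
        self.W = rng.uniform(-s, s, (n_in, 3 * hidden)).astype(np.float64)
        # Orthogonal recurrent blocks keep gradients alive over the
        # sequence; a negative update-gate bias starts the unit in a
        # remember-by-default regime.
        blocks = []
        for _ in range(3):
            a = rng.standard_normal((hidden, hidden))
            q, _r = np.linalg.qr(a)
            blocks.append(q)
        self.U = np.concatenate(blocks, axis=1).astype(np.float64)
        self.b = np.zeros(3 * hidden, dtype=np.float64)
        self.b[:hidden] = -1.0
        self.hidden = hidden

    @property
    def params(self) -> dict[str, np.ndarray]:
        return {"W": self.W, "U": self.U, "b": self.b}

    def forward(self, x: np.ndarray):
        """x: (B, T, n_in) -> final hidden (B, H) and a BPTT cache."""
        B, T, _ = x.shape
        H = self.hidden
        pre = x @ self.W + self.b  # (B,T,3H)
        h = np.zeros((B, H))
        zs = np.empty((T, B, H))
        rs = np.empty((T, B, H))
        cs = np.empty((T, B, H))
        hs = np.empty((T, B, H))  # h_{t-1}
        Uz, Ur, Uc = self.U[:, :H], self.U[:, H : 2 * H], self.U[:, 2 * H :]
        for t in range(T):
            hs[t] = h
            z = _sigmoid(pre[:, t, :H] + h @ Uz)
            r = _sigmoid(pre[:, t, H : 2 * H] + h @ Ur)
            c = np.tanh(pre[:, t, 2 * H :] + (r * h) @ Uc)
            h = (1.0 - z) * h + z * c
            zs[t], rs[t], cs[t] = z, r, c
        cache = (x, zs, rs, cs, hs)
        return h, cache

    def backward(self, dh: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradient of the loss w.r.t. parameters given dL/dh_final."""
        x, zs, rs, cs, hs = cache
        B, T, _ = x.shape
        H = self.hidden
        Uz, Ur, Uc = self.U[:, :H], self.U[:, H : 2 * H], self.U[:, 2 * H :]
        dU = np.zeros_like(self.U)
        dpre = np.empty((B, T, 3 * H))
        dh = dh.copy()
        for t in range(T - 1, -1, -1):
            z, r, c, hp = zs[t], rs[t], cs[t], hs[t]
            dz = dh * (c - hp)
            dc = dh * z
            dh_prev = dh * (1.0 - z)
            dpc = dc * (1.0 - c * c)
            drh = dpc @ Uc.T
            dr = drh * hp
            dh_prev += drh * r
            dpz = dz * z * (1.0 - z)
            dpr = dr * r * (1.0 - r)
            dU[:, :H] += hp.T @ dpz
            dU[:, H : 2 * H] += hp.T @ dpr
            dU[:, 2 * H :] += (r * hp).T @ dpc
            dh_prev += dpz @ Uz.T + dpr @ Ur.T
            dpre[:, t, :H] = dpz
            dpre[:, t, H : 2 * H] = dpr
            dpre[:, t, 2 * H :] = dpc
            dh = dh_prev
        n_in = x.shape[2]
        dW = x.reshape(B * T, n_in).T @ dpre.reshape(B * T, 3 * H)
        db = dpre.sum(axis=(0, 1))
        return {"W": dW, "U": dU, "b": db}


class TwoEncoderClassifier:
    """S-encoder + X-encoder -> concatenated hidden states -> linear head."""

    def __init__(
        self,
        n_in_s: int,
        n_in_x: int,
        hidden: int,
        n_labels: int,
        rng: np.random.Generator,
    ):
        self.enc_s = GRUEncoder(n_in_s, hidden, rng)
        self.enc_x = GRUEncoder(n_in_x, hidden, rng)
        s = 1.0 / np.sqrt(2 * hidden)
        self.Wo = rng.uniform(-s, s, (2 * hidden, n_labels))
        self.bo = np.zeros(n_labels)
        self.hidden = hidden
        self.n_labels = n_labels

    # -- parameter bookkeeping -------------------------------------------
    def named_params(self) -> dict[str, np.ndarray]:
        out = {}
        for prefix, enc in (("s", self.enc_s), ("x", self.enc_x)):
            for name, arr in enc.params.items():
                out[f"{prefix}.{name}"] = arr
        out["o.W"] = self.Wo
        out["o.b"] = self.bo
        return out

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        for name, arr in self.named_params().items():
            arr[...] = params[name]

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.named_params().items()}

    # -- forward / loss ---------------------------------------------------
    def logits(self, S: np.ndarray, X: np.ndarray):
        """S: (B, k, n_seeds), X: (B, L, n_feat) -> (B, n_labels)."""
        hs, cs = self.enc_s.forward(S)
        hx, cx = self.enc_x.forward(X)
        h = np.concatenate([hs, hx], axis=1)
        return h @ self.Wo + self.bo, (h, cs, cx)

    def predict_proba(self, S: np.ndarray, X: np.ndarray) -> np.ndarray:
        lg, _ = self.logits(S, X)
        lg = lg - lg.max(axis=1, keepdims=True)
        e = np.exp(lg)
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grads(self, S: np.ndarray, X: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and gradients for one batch."""
        B = S.shape[0]
        lg, (h, cs, cx) = self.logits(S, X)
        lg = lg - lg.max(axis=1, keepdims=True)
        e = np.exp(lg)
        p = e / e.sum(axis=1, keepdims=True)
        loss = -np.log(np.maximum(p[np.arange(B), y], 1e-12)).mean()
        dlg = p.copy()
        dlg[np.arange(B), y] -= 1.0
        dlg /= B
        grads = {
            "o.W": h.T @ dlg,
            "o.b": dlg.sum(axis=0),
        }
        dh = dlg @ self.Wo.T
        H = self.hidden
        gs = self.enc_s.backward(dh[:, :H], cs)
        gx = self.enc_x.backward(dh[:, H:], cx)
        for name, g in gs.items():
            grads[f"s.{name}"] = g
        for name, g in gx.items():
            grads[f"x.{name}"] = g
        return loss, grads


class AdamW:
    """Adam with decoupled weight decay (decay skipped on biases)."""

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.01,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            if self.wd and not k.endswith(".b") and not k.endswith("o.b"):
                p *= 1.0 - self.lr * self.wd
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
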