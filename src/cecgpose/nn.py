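"""Minimal NumPy neural-network core: peephole LSTM, bidirectional stacking,
softmax cross-entropy, and Adam.

The LSTM cell follows the peephole-gated formulation

    g_t = tanh( x_t W_xc + h_{t-1} W_hc + b_c )
    i_t = sigm( x_t W_xi + h_{t-1} W_hi + w_ci (.) c_{t-1} + b_i )
    f_t = sigm( x_t W_xf + h_{t-1} W_hf + w_cf (.) c_{t-1} + b_f )
    c_t = f_t (.) c_{t-1} + g_t (.) i_t
    o_t = sigm( x_t W_xo + h_{t-1} W_ho + w_co (.) c_{t-1} + b_o )
    h_t = o_t (.) tanh(c_t)

with diagonal (elementwise) peephole weights w_c* reading the *previous*
cell state in all three gates.  Gate activations are logistic sigmoids and
state activations tanh.

Implementation notes, driven by single-CPU throughput: sequences are
time-major (T, B, F) so every per-step slice is contiguous; the candidate
gate g and the sigmoid block [i, f, o] live in separate contiguous buffers;
input projections for all time steps are computed in one GEMM per block,
leaving only hidden-to-hidden products inside the time loop; the hot loops
use preallocated buffers and in-place ufuncs; compute is float32 (a float64
path exists for gradient checking).  Sigmoids are evaluated without range
clipping — float32 exp overflows to +inf for z < -88 and 1/(1+inf) is an
exact 0 — with overflow warnings suppressed around the loops.  All parameter
initialization is driven by an explicit ``numpy.random.Generator``, so
training is bit-reproducible.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LSTMDirParams", "lstm_forward", "lstm_backward", "BiLSTMNet", "Adam"]


@dataclass
class LSTMDirParams:
    """Parameters of one LSTM direction.

    The candidate (cell-input) gate g is kept separate; the three sigmoid
    gates are packed in order [i, f, o] along the last axis.  ``peep`` packs
    the diagonal peephole weights in the same [i, f, o] order.
    """

    W_xg: np.ndarray  # (F, H)
    W_xs: np.ndarray  # (F, 3H)
    W_hg: np.ndarray  # (H, H)
    W_hs: np.ndarray  # (H, 3H)
    b_g: np.ndarray  # (H,)
    b_s: np.ndarray  # (3H,)
    peep: np.ndarray  # (3H,)

    @property
    def hidden(self) -> int:
        return self.W_hg.shape[0]

    @classmethod
    def init(cls, n_in: int, hidden: int, rng: np.random.Generator, dtype=np.float32):
        k = 1.0 / np.sqrt(hidden)
        u = lambda shape: rng.uniform(-k, k, size=shape).astype(dtype)  # noqa: E731
        b_s = np.zeros(3 * hidden, dtype=dtype)
        b_s[hidden : 2 * hidden] = 1.0  # forget-gate bias: remember by default
        return cls(
            W_xg=u((n_in, hidden)),
            W_xs=u((n_in, 3 * hidden)),
            W_hg=u((hidden, hidden)),
            W_hs=u((hidden, 3 * hidden)),
            b_g=np.zeros(hidden, dtype=dtype),
            b_s=b_s,
            peep=np.zeros(3 * hidden, dtype=dtype),
        )

    def names(self):
        return ("W_xg", "W_xs", "W_hg", "W_hs", "b_g", "b_s", "peep")


def _ws_get(ws: dict | None, key: str, shape: tuple, dtype) -> np.ndarray:
    """Reusable uninitialized buffer from a workspace pool.

    Large arrays re-allocated every call cost more in page faults than the
    arithmetic performed on them, so the training loop hands each forward /
    backward pass a persistent pool keyed by buffer role and shape.
    """
    if ws is None:
        return np.empty(shape, dtype=dtype)
    full_key = (key, shape, np.dtype(dtype).str)
    buf = ws.get(full_key)
    if buf is None:
        buf = np.empty(shape, dtype=dtype)
        ws[full_key] = buf
    return buf


def lstm_forward(x: np.ndarray, p: LSTMDirParams, ws: dict | None = None, tag: str = ""):
    """Run one direction over time-major x (T, B, F); returns h (T, B, H) + cache."""
    T, B, F = x.shape
    H = p.hidden
    x2d = x.reshape(T * B, F)
    G = _ws_get(ws, tag + "G", (T, B, H), x.dtype)  # becomes tanh'd candidate in place
    np.matmul(x2d, p.W_xg, out=G.reshape(T * B, H))
    G += p.b_g
    S = _ws_get(ws, tag + "S", (T, B, 3 * H), x.dtype)  # becomes sigmoid block in place
    np.matmul(x2d, p.W_xs, out=S.reshape(T * B, 3 * H))
    S += p.b_s
    C = _ws_get(ws, tag + "C", (T, B, H), x.dtype)
    TC = _ws_get(ws, tag + "TC", (T, B, H), x.dtype)
    hs = _ws_get(ws, tag + "hs", (T, B, H), x.dtype)
    zeros = np.zeros((B, H), dtype=x.dtype)
    hWg = _ws_get(ws, tag + "hWg", (B, H), x.dtype)
    hWs = _ws_get(ws, tag + "hWs", (B, 3 * H), x.dtype)
    c3 = _ws_get(ws, tag + "c3", (B, 3 * H), x.dtype)
    tH = _ws_get(ws, tag + "tH", (B, H), x.dtype)
    h = zeros
    c_prev = zeros
    with np.errstate(over="ignore"):
        for t in range(T):
            g = G[t]
            s = S[t]
            np.matmul(h, p.W_hg, out=hWg)
            g += hWg
            np.matmul(h, p.W_hs, out=hWs)
            s += hWs
            c3[:, :H] = c_prev
            c3[:, H : 2 * H] = c_prev
            c3[:, 2 * H :] = c_prev
            c3 *= p.peep
            s += c3
            np.tanh(g, out=g)
            # in-place logistic sigmoid of the [i, f, o] block
            np.negative(s, out=s)
            np.exp(s, out=s)
            s += 1.0
            np.reciprocal(s, out=s)
            c = C[t]
            np.multiply(s[:, H : 2 * H], c_prev, out=c)  # f * c_prev
            np.multiply(g, s[:, :H], out=tH)  # g * i
            c += tH
            np.tanh(c, out=TC[t])
            np.multiply(s[:, 2 * H :], TC[t], out=hs[t])
            h = hs[t]
            c_prev = c
    cache = (x, G, S, C, TC, hs, zeros)
    return hs, cache


def lstm_backward(dh_seq: np.ndarray, cache, p: LSTMDirParams, ws: dict | None = None, tag: str = ""):
    """BPTT through one direction; dh_seq (T, B, H) is consumed (mutated)."""
    x, G, S, C, TC, hs, zeros = cache
    T, B, F = x.shape
    H = p.hidden
    dG = _ws_get(ws, tag + "dG", (T, B, H), x.dtype)
    dS = _ws_get(ws, tag + "dS", (T, B, 3 * H), x.dtype)
    dc = np.zeros((B, H), dtype=x.dtype)
    dh_next = np.zeros((B, H), dtype=x.dtype)
    dW_hg = np.zeros_like(p.W_hg)
    dW_hs = np.zeros_like(p.W_hs)
    dpeep = np.zeros_like(p.peep)
    W_hg_T = np.ascontiguousarray(p.W_hg.T)
    W_hs_T = np.ascontiguousarray(p.W_hs.T)
    t1 = np.empty((B, H), dtype=x.dtype)
    t2 = np.empty((B, H), dtype=x.dtype)
    c3 = np.empty((B, 3 * H), dtype=x.dtype)
    tWg = np.empty_like(dW_hg)
    tWs = np.empty_like(dW_hs)
    for t in range(T - 1, -1, -1):
        g = G[t]
        s = S[t]
        i = s[:, :H]
        f = s[:, H : 2 * H]
        o = s[:, 2 * H :]
        tc = TC[t]
        c_prev = C[t - 1] if t > 0 else zeros
        h_prev = hs[t - 1] if t > 0 else zeros
        dh = dh_seq[t]
        dh += dh_next
        ds = dS[t]
        dzi = ds[:, :H]
        dzf = ds[:, H : 2 * H]
        dzo = ds[:, 2 * H :]
        # output gate: dz_o = dh * tc * o * (1 - o)
        np.subtract(1.0, o, out=dzo)
        dzo *= o
        np.multiply(dh, tc, out=t1)
        dzo *= t1
        # cell: dc += dh * o * (1 - tc^2)
        np.multiply(tc, tc, out=t2)
        np.subtract(1.0, t2, out=t2)
        t2 *= o
        t2 *= dh
        dc += t2
        # forget gate: dz_f = dc * c_prev * f * (1 - f)
        np.subtract(1.0, f, out=dzf)
        dzf *= f
        np.multiply(dc, c_prev, out=t1)
        dzf *= t1
        # input gate: dz_i = dc * g * i * (1 - i)
        np.subtract(1.0, i, out=dzi)
        dzi *= i
        np.multiply(dc, g, out=t1)
        dzi *= t1
        # candidate: dz_g = dc * i * (1 - g^2)
        dg = dG[t]
        np.multiply(g, g, out=dg)
        np.subtract(1.0, dg, out=dg)
        np.multiply(dc, i, out=t1)
        dg *= t1
        # peephole gradients: sum_b dz_* (.) c_prev
        c3[:, :H] = c_prev
        c3[:, H : 2 * H] = c_prev
        c3[:, 2 * H :] = c_prev
        c3 *= ds
        dpeep += c3.sum(axis=0)
        # carry to t-1: dc = dc*f + dz_i p_i + dz_f p_f + dz_o p_o
        dc *= f
        np.multiply(ds, p.peep, out=c3)
        dc += c3[:, :H]
        dc += c3[:, H : 2 * H]
        dc += c3[:, 2 * H :]
        # recurrent gradients
        np.matmul(dg, W_hg_T, out=dh_next)
        np.matmul(ds, W_hs_T, out=t2)
        dh_next += t2
        np.matmul(h_prev.T, dg, out=tWg)
        dW_hg += tWg
        np.matmul(h_prev.T, ds, out=tWs)
        dW_hs += tWs
    dG2 = dG.reshape(T * B, H)
    dS2 = dS.reshape(T * B, 3 * H)
    x2d = x.reshape(T * B, F)
    grads = {
        "W_xg": x2d.T @ dG2,
        "W_xs": x2d.T @ dS2,
        "W_hg": dW_hg,
        "W_hs": dW_hs,
        "b_g": dG2.sum(axis=0),
        "b_s": dS2.sum(axis=0),
        "peep": dpeep,
    }
    dx = _ws_get(ws, tag + "dx", (T, B, F), x.dtype)
    np.matmul(dG2, p.W_xg.T, out=dx.reshape(T * B, F))
    dx2 = _ws_get(ws, tag + "dx2", (T, B, F), x.dtype)
    np.matmul(dS2, p.W_xs.T, out=dx2.reshape(T * B, F))
    dx += dx2
    return dx, grads


class BiLSTMNet:
    """Stacked bidirectional LSTM + dense softmax classifier.

    Each layer runs a forward and a backward pass over the sequence and
    concatenates their hidden sequences (so a layer of H units per direction
    outputs 2H features per step).  The classifier head reads the last
    forward state and the last backward state of the top layer.
    """

    def __init__(self, n_in: int, layer_sizes, n_classes: int, seed: int, dtype=np.float32):
        self.dtype = dtype
        self.layer_sizes = tuple(int(h) for h in layer_sizes)
        self.n_classes = int(n_classes)
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) % (2**31), 271828]))
        self.layers: list[tuple[LSTMDirParams, LSTMDirParams]] = []
        f_in = n_in
        for h in self.layer_sizes:
            fwd = LSTMDirParams.init(f_in, h, rng, dtype)
            bwd = LSTMDirParams.init(f_in, h, rng, dtype)
            self.layers.append((fwd, bwd))
            f_in = 2 * h
        k = 1.0 / np.sqrt(f_in)
        self.W_d = rng.uniform(-k, k, size=(f_in, n_classes)).astype(dtype)
        self.b_d = np.zeros(n_classes, dtype=dtype)
        self._ws: dict = {}  # buffer pool, keyed by (role, shape, dtype)

    # ---- parameter plumbing -------------------------------------------------

    def parameters(self) -> dict[str, np.ndarray]:
        out = {}
        for li, (fwd, bwd) in enumerate(self.layers):
            for tag, d in (("f", fwd), ("b", bwd)):
                for name in d.names():
                    out[f"l{li}{tag}.{name}"] = getattr(d, name)
        out["dense.W"] = self.W_d
        out["dense.b"] = self.b_d
        return out

    def set_parameters(self, params: dict[str, np.ndarray]) -> None:
        for li, (fwd, bwd) in enumerate(self.layers):
            for tag, d in (("f", fwd), ("b", bwd)):
                for name in d.names():
                    setattr(d, name, params[f"l{li}{tag}.{name}"])
        self.W_d = params["dense.W"]
        self.b_d = params["dense.b"]

    # ---- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False):
        """x (B, T, F) -> logits (B, n_classes); optionally keep caches."""
        x = np.ascontiguousarray(np.swapaxes(x, 0, 1), dtype=self.dtype)  # (T, B, F)
        ws = self._ws
        T, B, _ = x.shape
        caches = []
        for li, (fwd, bwd) in enumerate(self.layers):
            H = self.layer_sizes[li]
            h_f, cache_f = lstm_forward(x, fwd, ws, f"l{li}f_")
            x_rev = _ws_get(ws, f"l{li}_xrev", x.shape, self.dtype)
            x_rev[:] = x[::-1]
            h_b_rev, cache_b = lstm_forward(x_rev, bwd, ws, f"l{li}b_")
            h_b = h_b_rev[::-1]
            x = _ws_get(ws, f"l{li}_xcat", (T, B, 2 * H), self.dtype)
            x[:, :, :H] = h_f
            x[:, :, H:] = h_b
            if keep_cache:
                caches.append((cache_f, cache_b))
        H_top = self.layer_sizes[-1]
        feats = np.concatenate([x[-1, :, :H_top], x[0, :, H_top:]], axis=1)
        logits = feats @ self.W_d + self.b_d
        if keep_cache:
            self._cache = (caches, feats, x.shape)
        return logits

    def backward(self, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        caches, feats, top_shape = self._cache
        H_top = self.layer_sizes[-1]
        grads = {
            "dense.W": feats.T @ dlogits,
            "dense.b": dlogits.sum(axis=0),
        }
        dfeats = dlogits @ self.W_d.T
        dx = np.zeros(top_shape, dtype=self.dtype)  # (T, B, 2H_top)
        dx[-1, :, :H_top] = dfeats[:, :H_top]
        dx[0, :, H_top:] = dfeats[:, H_top:]
        ws = self._ws
        T, B, _ = top_shape
        for li in range(len(self.layers) - 1, -1, -1):
            fwd, bwd = self.layers[li]
            cache_f, cache_b = caches[li]
            H = self.layer_sizes[li]
            dh_f = _ws_get(ws, f"l{li}_dhf", (T, B, H), self.dtype)
            dh_f[:] = dx[:, :, :H]
            dh_b_rev = _ws_get(ws, f"l{li}_dhb", (T, B, H), self.dtype)
            dh_b_rev[:] = dx[::-1, :, H:]
            dx_f, g_f = lstm_backward(dh_f, cache_f, fwd, ws, f"l{li}f_")
            dx_b_rev, g_b = lstm_backward(dh_b_rev, cache_b, bwd, ws, f"l{li}b_")
            dx = dx_f
            dx += dx_b_rev[::-1]
            for name, g in g_f.items():
                grads[f"l{li}f.{name}"] = g
            for name, g in g_b.items():
                grads[f"l{li}b.{name}"] = g
        self._cache = None
        return grads

    # ---- loss ---------------------------------------------------------------

    @staticmethod
    def softmax(logits: np.ndarray) -> np.ndarray:
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z.astype(np.float64))
        return e / e.sum(axis=1, keepdims=True)

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy and parameter gradients for one batch."""
        logits = self.forward(x, keep_cache=True)
        probs = self.softmax(logits)
        B = len(y)
        loss = float(-np.mean(np.log(probs[np.arange(B), y] + 1e-12)))
        dlogits = probs.astype(self.dtype)
        dlogits[np.arange(B), y] -= 1.0
        dlogits /= B
        grads = self.backward(dlogits)
        return loss, grads


class Adam:
    """Adam with the standard bias correction."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, p in params.items():
            g = grads[k].astype(np.float32)
            m = self.m[k]
            v = self.v[k]
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= (self.lr / b1t) * m / (np.sqrt(v / b2t) + self.eps)
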