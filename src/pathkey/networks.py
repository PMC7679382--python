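"""Small trainable token-classification networks, implemented in numpy.

Three desk-scale architectures share one interface: an embedding layer maps
subword ids to vectors, an encoder produces one state per token, and a
linear head scores the four keyword classes per token. Backpropagation is
written by hand and verified against finite differences in the test suite.

* :class:`RecurrentTagger` — embedding, a tanh recurrent layer, linear head.
* :class:`ConvTagger` — embedding, two width-3 convolution layers with ReLU,
  linear head.
* :class:`TransformerTagger` — a tiny from-scratch pre-LN transformer
  encoder (default 2 layers, 128 hidden, 2 heads) with learned positional
  embeddings.

All computation is float64; these models target corpora of thousands of
short statements, not GPU-scale workloads.
"""

from __future__ import annotations

import numpy as np

from .classes import N_CLASSES

__all__ = ["Adam", "NeuralTagger", "RecurrentTagger", "ConvTagger",
           "TransformerTagger", "softmax", "masked_cross_entropy"]

PAD_ID = 0


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def masked_cross_entropy(
    logits: np.ndarray, targets: np.ndarray, mask: np.ndarray,
) -> tuple[float, np.ndarray]:
    """Mean token-level cross-entropy over unmasked positions.

    Returns the scalar loss and its gradient with respect to the logits.
    """
    p = softmax(logits)
    n = max(mask.sum(), 1.0)
    picked = np.take_along_axis(p, targets[..., None], axis=-1)[..., 0]
    loss = -(np.log(np.maximum(picked, 1e-300)) * mask).sum() / n
    grad = p.copy()
    np.put_along_axis(
        grad, targets[..., None],
        np.take_along_axis(grad, targets[..., None], axis=-1) - 1.0, axis=-1)
    grad *= (mask / n)[..., None]
    return float(loss), grad


class Adam:
    """Adam optimizer over a named parameter dictionary."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            if k not in self.params:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class NeuralTagger:
    """Shared surface: id mapping, tagging head, batching, pooling.

    Subclasses define the encoder through ``forward_states`` (ids -> one
    state vector per token, plus a cache) and ``backward_states`` (state
    gradients -> parameter gradients, including the embedding).
    """

    architecture = "base"

    def __init__(self, vocab_entries, state_dim: int, seed: int = 0,
                 n_classes: int = N_CLASSES, unknown_token: str = "[UNK]"):
        # id 0 is reserved for padding
        self.id_of = {tok: i + 1 for i, tok in enumerate(vocab_entries)}
        self.unknown_id = self.id_of.get(unknown_token, 1)
        self.n_ids = len(self.id_of) + 1
        self.state_dim = state_dim
        self.n_classes = n_classes
        self.seed = seed
        self.params: dict[str, np.ndarray] = {}
        self.history: list[float] = []

    # -- encoder contract -------------------------------------------------
    def forward_states(self, X: np.ndarray, mask: np.ndarray):
        raise NotImplementedError

    def backward_states(self, cache, dH: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    # -- head --------------------------------------------------------------
    def _init_head(self, rng: np.random.Generator) -> None:
        s = 1.0 / np.sqrt(self.state_dim)
        self.params["Wo"] = rng.normal(0, s, (self.state_dim,
                                              self.n_classes))
        self.params["bo"] = np.zeros(self.n_classes)

    def head_param_names(self) -> tuple[str, ...]:
        return ("Wo", "bo")

    def encoder_param_names(self) -> tuple[str, ...]:
        return tuple(k for k in self.params if k not in
                     self.head_param_names())

    # -- batching ----------------------------------------------------------
    def ids_of(self, tokens) -> np.ndarray:
        return np.array([self.id_of.get(t, self.unknown_id) for t in tokens],
                        dtype=np.int64)

    def pad_batch(self, token_seqs) -> tuple[np.ndarray, np.ndarray]:
        T = max((len(s) for s in token_seqs), default=0)
        T = max(T, 1)
        B = len(token_seqs)
        X = np.full((B, T), PAD_ID, dtype=np.int64)
        mask = np.zeros((B, T))
        for i, seq in enumerate(token_seqs):
            ids = self.ids_of(seq)
            X[i, :len(ids)] = ids
            mask[i, :len(ids)] = 1.0
        return X, mask

    # -- tagging -----------------------------------------------------------
    def logits(self, X: np.ndarray, mask: np.ndarray):
        H, cache = self.forward_states(X, mask)
        return H @ self.params["Wo"] + self.params["bo"], H, cache

    def loss_and_grads(self, X, mask, Y):
        logits, H, cache = self.logits(X, mask)
        loss, dlogits = masked_cross_entropy(logits, Y, mask)
        grads = {"Wo": np.einsum("bth,btc->hc", H, dlogits),
                 "bo": dlogits.sum(axis=(0, 1))}
        dH = dlogits @ self.params["Wo"].T
        grads.update(self.backward_states(cache, dH))
        return loss, grads

    def predict_logits(self, tokens) -> np.ndarray:
        """Pre-softmax class scores p_ij^l, one row per token."""
        if len(tokens) == 0:
            return np.zeros((0, self.n_classes))
        X, mask = self.pad_batch([list(tokens)])
        logits, _, _ = self.logits(X, mask)
        return logits[0, : len(tokens), :]

    # -- sequence embedding for sentence-pair pre-training ------------------
    def encode_mean(self, X, mask):
        """Masked mean of token states; cache kept for the backward pass."""
        H, cache = self.forward_states(X, mask)
        denom = np.maximum(mask.sum(axis=1, keepdims=True), 1.0)
        hbar = (H * mask[..., None]).sum(axis=1) / denom
        return hbar, (cache, mask, denom)

    def backward_encode_mean(self, pool_cache, dhbar):
        cache, mask, denom = pool_cache
        dH = (dhbar[:, None, :] / denom[..., None]) * mask[..., None]
        return self.backward_states(cache, dH)


class RecurrentTagger(NeuralTagger):
    """Embedding -> tanh recurrent layer -> per-token linear head."""

    architecture = "recurrent"

    def __init__(self, vocab_entries, embed_dim: int = 32,
                 hidden_dim: int = 64, seed: int = 0,
                 n_classes: int = N_CLASSES, unknown_token: str = "[UNK]"):
        super().__init__(vocab_entries, hidden_dim, seed, n_classes,
                         unknown_token)
        self.embed_dim = embed_dim
        rng = np.random.default_rng(seed)
        self.params["E"] = rng.normal(0, 0.1, (self.n_ids, embed_dim))
        self.params["Wx"] = rng.normal(0, 1 / np.sqrt(embed_dim),
                                       (embed_dim, hidden_dim))
        self.params["Wh"] = rng.normal(0, 1 / np.sqrt(hidden_dim),
                                       (hidden_dim, hidden_dim))
        self.params["bh"] = np.zeros(hidden_dim)
        self._init_head(rng)

    def forward_states(self, X, mask):
        E, Wx, Wh, bh = (self.params[k] for k in ("E", "Wx", "Wh", "bh"))
        B, T = X.shape
        emb = E[X]
        H = np.empty((B, T, Wh.shape[0]))
        h = np.zeros((B, Wh.shape[0]))
        pre = emb @ Wx + bh
        for t in range(T):
            h = np.tanh(pre[:, t] + h @ Wh)
            H[:, t] = h
        return H, (X, emb, H)

    def backward_states(self, cache, dH):
        X, emb, H = cache
        Wx, Wh = self.params["Wx"], self.params["Wh"]
        B, T, h_dim = dH.shape
        dWx = np.zeros_like(Wx)
        dWh = np.zeros_like(Wh)
        dbh = np.zeros(h_dim)
        demb = np.zeros_like(emb)
        dh_next = np.zeros((B, h_dim))
        for t in range(T - 1, -1, -1):
            dh = dH[:, t] + dh_next
            da = dh * (1.0 - H[:, t] ** 2)
            dWx += emb[:, t].T @ da
            h_prev = H[:, t - 1] if t > 0 else np.zeros((B, h_dim))
            dWh += h_prev.T @ da
            dbh += da.sum(axis=0)
            demb[:, t] = da @ Wx.T
            dh_next = da @ Wh.T
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, X, demb)
        return {"E": dE, "Wx": dWx, "Wh": dWh, "bh": dbh}


class ConvTagger(NeuralTagger):
    """Embedding -> two width-3 ReLU convolution layers -> linear head.

    Max pooling is omitted: the head must stay per-token for tagging.
    """

    architecture = "convolutional"

    def __init__(self, vocab_entries, embed_dim: int = 32,
                 channels: int = 64, seed: int = 0,
                 n_classes: int = N_CLASSES, unknown_token: str = "[UNK]"):
        super().__init__(vocab_entries, channels, seed, n_classes,
                         unknown_token)
        self.embed_dim = embed_dim
        rng = np.random.default_rng(seed)
        self.params["E"] = rng.normal(0, 0.1, (self.n_ids, embed_dim))
        self.params["W1"] = rng.normal(0, 1 / np.sqrt(3 * embed_dim),
                                       (3, embed_dim, channels))
        self.params["b1"] = np.zeros(channels)
        self.params["W2"] = rng.normal(0, 1 / np.sqrt(3 * channels),
                                       (3, channels, channels))
        self.params["b2"] = np.zeros(channels)
        self._init_head(rng)

    @staticmethod
    def _conv(x, W, b):
        # same-padded width-3 convolution: y[t] = sum_o x[t+o-1] @ W[o] + b
        B, T, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (0, 0)))
        y = np.zeros((B, T, W.shape[2]))
        for o in range(3):
            y += xp[:, o:o + T] @ W[o]
        return y + b

    @staticmethod
    def _conv_backward(x, W, dy):
        B, T, _ = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (0, 0)))
        dW = np.zeros_like(W)
        dxp = np.zeros_like(xp)
        for o in range(3):
            dW[o] = np.einsum("btd,btc->dc", xp[:, o:o + T], dy)
            dxp[:, o:o + T] += dy @ W[o].T
        return dW, dy.sum(axis=(0, 1)), dxp[:, 1:T + 1]

    def forward_states(self, X, mask):
        E, W1, b1, W2, b2 = (self.params[k]
                             for k in ("E", "W1", "b1", "W2", "b2"))
        emb = E[X]
        pre1 = self._conv(emb, W1, b1)
        h1 = np.maximum(pre1, 0.0)
        pre2 = self._conv(h1, W2, b2)
        h2 = np.maximum(pre2, 0.0)
        return h2, (X, emb, pre1, h1, pre2)

    def backward_states(self, cache, dH):
        X, emb, pre1, h1, pre2 = cache
        dpre2 = dH * (pre2 > 0)
        dW2, db2, dh1 = self._conv_backward(h1, self.params["W2"], dpre2)
        dpre1 = dh1 * (pre1 > 0)
        dW1, db1, demb = self._conv_backward(emb, self.params["W1"], dpre1)
        dE = np.zeros_like(self.params["E"])
        np.add.at(dE, X, demb)
        return {"E": dE, "W1": dW1, "b1": db1, "W2": dW2, "b2": db2}


def _layer_norm(x, g, b):
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + 1e-6)
    xhat = (x - mu) * inv
    return xhat * g + b, (xhat, inv, g)


def _layer_norm_backward(dy, cache):
    xhat, inv, g = cache
    dg = (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
    db = dy.sum(axis=tuple(range(dy.ndim - 1)))
    dxhat = dy * g
    dx = inv * (dxhat - dxhat.mean(axis=-1, keepdims=True)
                - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True))
    return dx, dg, db


class TransformerTagger(NeuralTagger):
    """Tiny from-scratch pre-LN transformer encoder with a token head.

    Defaults (2 layers, 128 hidden, 2 heads) are the desk-scale encoder;
    ``TransformerTagger.full_scale_preset`` carries the standard full-scale
    dimensions of the encoder family (12 layers, 768 hidden, 12 heads) for
    configuration completeness, not for training in this package.
    """

    architecture = "transformer"
    full_scale_preset = {"n_layers": 12, "model_dim": 768, "n_heads": 12,
                         "learning_rate": 2e-5, "batch_size": 16}

    def __init__(self, vocab_entries, model_dim: int = 128,
                 n_layers: int = 2, n_heads: int = 2, ff_dim: int | None
                 = None, max_len: int = 512, seed: int = 0,
                 n_classes: int = N_CLASSES, unknown_token: str = "[UNK]"):
        super().__init__(vocab_entries, model_dim, seed, n_classes,
                         unknown_token)
        if model_dim % n_heads:
            raise ValueError("model_dim must be divisible by n_heads")
        self.n_layers, self.n_heads = n_layers, n_heads
        self.ff_dim = ff_dim or 2 * model_dim
        self.max_len = max_len
        rng = np.random.default_rng(seed)
        D, F = model_dim, self.ff_dim
        s = 1.0 / np.sqrt(D)
        p = self.params
        p["E"] = rng.normal(0, 0.02, (self.n_ids, D))
        p["P"] = rng.normal(0, 0.02, (max_len, D))
        for i in range(n_layers):
            for w in ("Wq", "Wk", "Wv", "Wa"):
                p[f"{w}{i}"] = rng.normal(0, s, (D, D))
            for bname in ("bq", "bk", "bv", "ba"):
                p[f"{bname}{i}"] = np.zeros(D)
            p[f"g1_{i}"], p[f"b1_{i}"] = np.ones(D), np.zeros(D)
            p[f"g2_{i}"], p[f"b2_{i}"] = np.ones(D), np.zeros(D)
            p[f"Wf1_{i}"] = rng.normal(0, s, (D, F))
            p[f"bf1_{i}"] = np.zeros(F)
            p[f"Wf2_{i}"] = rng.normal(0, 1 / np.sqrt(F), (F, D))
            p[f"bf2_{i}"] = np.zeros(D)
        p["gf"], p["bf"] = np.ones(D), np.zeros(D)
        self._init_head(rng)

    def _split_heads(self, x):
        B, T, D = x.shape
        return x.reshape(B, T, self.n_heads, D // self.n_heads) \
                .transpose(0, 2, 1, 3)

    def _merge_heads(self, x):
        B, Hh, T, dk = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, Hh * dk)

    def forward_states(self, X, mask):
        p = self.params
        B, T = X.shape
        x = p["E"][X] + p["P"][:T]
        key_bias = (1.0 - mask)[:, None, None, :] * (-1e9)
        caches = [(X,)]
        for i in range(self.n_layers):
            u, ln1 = _layer_norm(x, p[f"g1_{i}"], p[f"b1_{i}"])
            q = self._split_heads(u @ p[f"Wq{i}"] + p[f"bq{i}"])
            k = self._split_heads(u @ p[f"Wk{i}"] + p[f"bk{i}"])
            v = self._split_heads(u @ p[f"Wv{i}"] + p[f"bv{i}"])
            dk = q.shape[-1]
            S = q @ k.transpose(0, 1, 3, 2) / np.sqrt(dk) + key_bias
            A = softmax(S)
            ctx = self._merge_heads(A @ v)
            att = ctx @ p[f"Wa{i}"] + p[f"ba{i}"]
            x1 = x + att
            u2, ln2 = _layer_norm(x1, p[f"g2_{i}"], p[f"b2_{i}"])
            pre = u2 @ p[f"Wf1_{i}"] + p[f"bf1_{i}"]
            f = np.maximum(pre, 0.0)
            x = x1 + f @ p[f"Wf2_{i}"] + p[f"bf2_{i}"]
            caches.append((u, ln1, q, k, v, A, ctx, x1, u2, ln2, pre, f))
        H, lnf = _layer_norm(x, p["gf"], p["bf"])
        caches.append(lnf)
        return H, caches

    def backward_states(self, caches, dH):
        p = self.params
        grads: dict[str, np.ndarray] = {}
        lnf = caches[-1]
        dx, grads["gf"], grads["bf"] = _layer_norm_backward(dH, lnf)
        for i in range(self.n_layers - 1, -1, -1):
            u, ln1, q, k, v, A, ctx, x1, u2, ln2, pre, f = caches[i + 1]
            # FFN branch
            df = dx @ p[f"Wf2_{i}"].T
            grads[f"Wf2_{i}"] = np.einsum("btf,btd->fd", f, dx)
            grads[f"bf2_{i}"] = dx.sum(axis=(0, 1))
            dpre = df * (pre > 0)
            grads[f"Wf1_{i}"] = np.einsum("btd,btf->df", u2, dpre)
            grads[f"bf1_{i}"] = dpre.sum(axis=(0, 1))
            du2 = dpre @ p[f"Wf1_{i}"].T
            dx1_ln, grads[f"g2_{i}"], grads[f"b2_{i}"] = \
                _layer_norm_backward(du2, ln2)
            dx1 = dx + dx1_ln
            # attention branch
            datt = dx1
            grads[f"Wa{i}"] = np.einsum("btd,bte->de", ctx, datt)
            grads[f"ba{i}"] = datt.sum(axis=(0, 1))
            dctx = self._split_heads(datt @ p[f"Wa{i}"].T)
            dA = dctx @ v.transpose(0, 1, 3, 2)
            dv = A.transpose(0, 1, 3, 2) @ dctx
            dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
            dk_dim = q.shape[-1]
            dq = dS @ k / np.sqrt(dk_dim)
            dk_ = dS.transpose(0, 1, 3, 2) @ q / np.sqrt(dk_dim)
            du = np.zeros_like(u)
            for W, b, dz in ((f"Wq{i}", f"bq{i}", dq),
                             (f"Wk{i}", f"bk{i}", dk_),
                             (f"Wv{i}", f"bv{i}", dv)):
                dz_m = self._merge_heads(dz)
                grads[W] = np.einsum("btd,bte->de", u, dz_m)
                grads[b] = dz_m.sum(axis=(0, 1))
                du += dz_m @ p[W].T
            dx_ln, grads[f"g1_{i}"], grads[f"b1_{i}"] = \
                _layer_norm_backward(du, ln1)
            dx = dx1 + dx_ln
        (X,) = caches[0]
        T = X.shape[1]
        dE = np.zeros_like(p["E"])
        np.add.at(dE, X, dx)
        dP = np.zeros_like(p["P"])
        dP[:T] = dx.sum(axis=0)
        grads["E"] = dE
        grads["P"] = dP
        return grads
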