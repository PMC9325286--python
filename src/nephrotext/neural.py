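"""Small neural text classifiers trained jointly with word embeddings.

Two architectures predict a diagnostic group from a token sequence:

* **CNN**: embedding -> 1-D convolution (32 kernels of width 3, ReLU) ->
  global max pooling -> dense ReLU layer -> dense softmax layer.
* **BiLSTM**: embedding -> one bidirectional LSTM layer; the final hidden
  states of both directions are concatenated and fed to a softmax head.

Both are implemented directly in numpy with manual backpropagation and the
Adam optimiser, so they run anywhere numpy runs and stay exactly
reproducible for a fixed seed.  Word embeddings are trained jointly with
the classifier objective (softmax cross-entropy).  Sequences are padded /
truncated to a configurable maximum length; padding positions are masked
out of the recurrence (the CNN sees a zero-initialised but trainable pad
embedding, which global max pooling makes irrelevant in practice).

These models are intentionally small: the corpora here are hundreds of
documents, not millions, and at that scale a compact network trained for a
few dozen epochs is the honest capacity ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .preprocess import TokenDoc

__all__ = ["SequenceEncoder", "CNNTextClassifier", "BiLSTMTextClassifier"]

PAD = 0
UNK = 1


@dataclass
class SequenceEncoder:
    """Token -> integer-id sequences with padding and truncation."""

    vocab: dict[str, int] = field(default_factory=dict)
    max_len: int = 0

    @classmethod
    def fit(cls, docs: Sequence[TokenDoc], max_len: Optional[int] = None,
            length_percentile: float = 95.0) -> "SequenceEncoder":
        vocab: dict[str, int] = {}
        lengths = []
        for d in docs:
            lengths.append(len(d.tokens))
            for t in d.tokens:
                if t not in vocab:
                    vocab[t] = len(vocab) + 2  # 0=PAD, 1=UNK
        if max_len is None:
            max_len = max(1, int(np.percentile([l for l in lengths if l > 0] or [1],
                                               length_percentile)))
        return cls(vocab=vocab, max_len=int(max_len))

    @property
    def vocab_size(self) -> int:
        return len(self.vocab) + 2

    def transform(self, docs: Sequence[TokenDoc]) -> np.ndarray:
        X = np.full((len(docs), self.max_len), PAD, dtype=np.int64)
        for i, d in enumerate(docs):
            ids = [self.vocab.get(t, UNK) for t in d.tokens[: self.max_len]]
            X[i, : len(ids)] = ids
        return X


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


class _Adam:
    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-2,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mh = self.m[k] / (1 - self.b1 ** self.t)
            vh = self.v[k] / (1 - self.b2 ** self.t)
            self.params[k] -= self.lr * mh / (np.sqrt(vh) + self.eps)


class _NeuralBase:
    """Shared fit/predict loop; subclasses provide forward/backward."""

    def __init__(self, n_classes: int, embed_dim: int = 32, seed: int = 0,
                 epochs: int = 30, batch_size: int = 32, lr: float = 1e-2):
        self.n_classes = n_classes
        self.embed_dim = embed_dim
        self.seed = seed
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.encoder: Optional[SequenceEncoder] = None
        self.params: dict[str, np.ndarray] = {}

    # subclass API ---------------------------------------------------------
    def _init_params(self, rng: np.random.Generator, vocab_size: int) -> None:
        raise NotImplementedError

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        raise NotImplementedError

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    # ----------------------------------------------------------------------
    def fit(self, docs: Sequence[TokenDoc], y: np.ndarray,
            max_len: Optional[int] = None) -> "_NeuralBase":
        rng = np.random.default_rng(self.seed)
        keep = [i for i, d in enumerate(docs) if len(d.tokens) > 0]
        if len(keep) < len(docs):
            import warnings

            warnings.warn(f"dropping {len(docs) - len(keep)} empty documents")
        docs = [docs[i] for i in keep]
        y = np.asarray(y)[keep]
        self.encoder = SequenceEncoder.fit(docs, max_len=max_len)
        X = self.encoder.transform(docs)
        self._init_params(rng, self.encoder.vocab_size)
        opt = _Adam(self.params, lr=self.lr)
        n = X.shape[0]
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                probs, cache = self._forward(X[idx], train=True)
                dlogits = probs.copy()
                dlogits[np.arange(idx.size), y[idx]] -= 1.0
                dlogits /= idx.size
                grads = self._backward(cache, dlogits)
                opt.step(grads)
        return self

    def predict_proba(self, docs: Sequence[TokenDoc]) -> np.ndarray:
        assert self.encoder is not None, "fit first"
        X = self.encoder.transform(docs)
        probs, _ = self._forward(X, train=False)
        return probs

    def predict(self, docs: Sequence[TokenDoc]) -> np.ndarray:
        return self.predict_proba(docs).argmax(axis=1)

    def score_train_accuracy(self, docs: Sequence[TokenDoc], y: np.ndarray) -> float:
        keep = [i for i, d in enumerate(docs) if len(d.tokens) > 0]
        return float(
            (self.predict([docs[i] for i in keep]) == np.asarray(y)[keep]).mean()
        )


class CNNTextClassifier(_NeuralBase):
    """Embedding -> conv1d(32 kernels, width 3, ReLU) -> max pool ->
    dense ReLU -> dense softmax."""

    def __init__(self, n_classes: int, embed_dim: int = 32, n_kernels: int = 32,
                 kernel_width: int = 3, hidden: int = 32, **kw):
        super().__init__(n_classes, embed_dim=embed_dim, **kw)
        self.n_kernels = n_kernels
        self.kernel_width = kernel_width
        self.hidden = hidden

    def _init_params(self, rng: np.random.Generator, vocab_size: int) -> None:
        d, F, w, h, K = (self.embed_dim, self.n_kernels, self.kernel_width,
                         self.hidden, self.n_classes)
        s = lambda *shape: rng.normal(0, 0.1, size=shape)
        self.params = {
            "E": s(vocab_size, d),
            "Wc": s(w, d, F),
            "bc": np.zeros(F),
            "W1": s(F, h),
            "b1": np.zeros(h),
            "W2": s(h, K),
            "b2": np.zeros(K),
        }
        self.params["E"][PAD] = 0.0

    def parameter_count(self, vocab_size: int) -> int:
        d, F, w, h, K = (self.embed_dim, self.n_kernels, self.kernel_width,
                         self.hidden, self.n_classes)
        return vocab_size * d + (w * d * F + F) + (F * h + h) + (h * K + K)

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        p = self.params
        B, L = X.shape
        w = self.kernel_width
        if L < w:  # pad up so at least one window exists
            X = np.concatenate([X, np.full((B, w - L), PAD)], axis=1)
            L = w
        emb = p["E"][X]                                  # (B, L, d)
        Z = sum(emb[:, j : L - w + 1 + j, :] @ p["Wc"][j] for j in range(w))
        Z = Z + p["bc"]                                  # (B, T, F)
        A = np.maximum(Z, 0.0)
        pool_arg = A.argmax(axis=1)                      # (B, F)
        pooled = A.max(axis=1)                           # (B, F)
        H1 = np.maximum(pooled @ p["W1"] + p["b1"], 0.0)
        logits = H1 @ p["W2"] + p["b2"]
        probs = _softmax(logits)
        cache = dict(X=X, emb=emb, Z=Z, pool_arg=pool_arg, pooled=pooled, H1=H1)
        return probs, cache

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        X, emb, Z = cache["X"], cache["emb"], cache["Z"]
        B, L, d = emb.shape
        w = self.kernel_width
        T = L - w + 1
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["W2"] = cache["H1"].T @ dlogits
        grads["b2"] = dlogits.sum(0)
        dH1 = dlogits @ p["W2"].T
        dH1[cache["H1"] <= 0] = 0.0
        grads["W1"] = cache["pooled"].T @ dH1
        grads["b1"] = dH1.sum(0)
        dpool = dH1 @ p["W1"].T                          # (B, F)
        dA = np.zeros((B, T, p["bc"].size))
        bi = np.arange(B)[:, None]
        fi = np.arange(p["bc"].size)[None, :]
        dA[bi, cache["pool_arg"], fi] = dpool
        dZ = dA * (Z > 0)
        grads["bc"] = dZ.sum(axis=(0, 1))
        demb = np.zeros_like(emb)
        for j in range(w):
            grads["Wc"][j] = np.einsum("btd,btf->df", emb[:, j : T + j, :], dZ)
            demb[:, j : T + j, :] += dZ @ p["Wc"][j].T
        np.add.at(grads["E"], X, demb)
        return grads


class BiLSTMTextClassifier(_NeuralBase):
    """Embedding -> bidirectional LSTM -> concatenated final states ->
    softmax head."""

    def __init__(self, n_classes: int, embed_dim: int = 32, hidden: int = 32, **kw):
        super().__init__(n_classes, embed_dim=embed_dim, **kw)
        self.hidden = hidden

    def _init_params(self, rng: np.random.Generator, vocab_size: int) -> None:
        d, H, K = self.embed_dim, self.hidden, self.n_classes
        s = lambda *shape: rng.normal(0, 0.1, size=shape)
        self.params = {"E": s(vocab_size, d)}
        for dr in ("f", "b"):
            self.params[f"Wx_{dr}"] = s(d, 4 * H)
            self.params[f"Wh_{dr}"] = s(H, 4 * H)
            bias = np.zeros(4 * H)
            bias[H : 2 * H] = 1.0  # forget-gate bias
            self.params[f"b_{dr}"] = bias
        self.params["Wo"] = s(2 * H, K)
        self.params["bo"] = np.zeros(K)

    @staticmethod
    def _reverse_rows(X: np.ndarray) -> np.ndarray:
        """Reverse the real (non-pad) prefix of each row, pads stay at end."""
        out = np.full_like(X, PAD)
        for i, row in enumerate(X):
            n = int((row != PAD).sum())
            out[i, :n] = row[:n][::-1]
        return out

    def _run_lstm(self, X: np.ndarray, direction: str) -> tuple[np.ndarray, list]:
        p = self.params
        H = self.hidden
        B, L = X.shape
        emb = p["E"][X]
        mask = (X != PAD).astype(float)
        h = np.zeros((B, H))
        c = np.zeros((B, H))
        caches = []
        Wx, Wh, b = p[f"Wx_{direction}"], p[f"Wh_{direction}"], p[f"b_{direction}"]
        for t in range(L):
            x_t = emb[:, t, :]
            m = mask[:, t : t + 1]
            z = x_t @ Wx + h @ Wh + b
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H : 2 * H])
            g = np.tanh(z[:, 2 * H : 3 * H])
            o = _sigmoid(z[:, 3 * H :])
            c_new = f * c + i * g
            h_new = o * np.tanh(c_new)
            caches.append(dict(x=x_t, h_prev=h, c_prev=c, i=i, f=f, g=g, o=o,
                               c_new=c_new, m=m, tok=X[:, t]))
            c = m * c_new + (1 - m) * c
            h = m * h_new + (1 - m) * h
        return h, caches

    def _backprop_lstm(self, dh_final: np.ndarray, caches: list, direction: str,
                       grads: dict[str, np.ndarray]) -> None:
        p = self.params
        H = self.hidden
        Wx, Wh = p[f"Wx_{direction}"], p[f"Wh_{direction}"]
        dh = dh_final
        dc = np.zeros_like(dh_final)
        for cache in reversed(caches):
            m = cache["m"]
            dh_new = dh * m
            dh_prev = dh * (1 - m)
            dc_new = dc * m
            dc_prev = dc * (1 - m)
            tanh_c = np.tanh(cache["c_new"])
            do = dh_new * tanh_c
            dc_new = dc_new + dh_new * cache["o"] * (1 - tanh_c ** 2)
            di = dc_new * cache["g"]
            df = dc_new * cache["c_prev"]
            dg = dc_new * cache["i"]
            dc_prev = dc_prev + dc_new * cache["f"]
            dz = np.concatenate(
                [
                    di * cache["i"] * (1 - cache["i"]),
                    df * cache["f"] * (1 - cache["f"]),
                    dg * (1 - cache["g"] ** 2),
                    do * cache["o"] * (1 - cache["o"]),
                ],
                axis=1,
            )
            grads[f"Wx_{direction}"] += cache["x"].T @ dz
            grads[f"Wh_{direction}"] += cache["h_prev"].T @ dz
            grads[f"b_{direction}"] += dz.sum(0)
            np.add.at(grads["E"], cache["tok"], dz @ Wx.T)
            dh = dh_prev + dz @ Wh.T
            dc = dc_prev

    def _forward(self, X: np.ndarray, train: bool) -> tuple[np.ndarray, dict]:
        Xr = self._reverse_rows(X)
        h_f, cache_f = self._run_lstm(X, "f")
        h_b, cache_b = self._run_lstm(Xr, "b")
        feat = np.concatenate([h_f, h_b], axis=1)
        logits = feat @ self.params["Wo"] + self.params["bo"]
        probs = _softmax(logits)
        return probs, dict(cache_f=cache_f, cache_b=cache_b, feat=feat)

    def _backward(self, cache: dict, dlogits: np.ndarray) -> dict[str, np.ndarray]:
        p = self.params
        H = self.hidden
        grads = {k: np.zeros_like(v) for k, v in p.items()}
        grads["Wo"] = cache["feat"].T @ dlogits
        grads["bo"] = dlogits.sum(0)
        dfeat = dlogits @ p["Wo"].T
        self._backprop_lstm(dfeat[:, :H], cache["cache_f"], "f", grads)
        self._backprop_lstm(dfeat[:, H:], cache["cache_b"], "b", grads)
        return grads
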