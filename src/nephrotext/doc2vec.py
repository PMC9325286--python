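"""Distributed document representations via PV-DBOW with negative sampling.

Each document owns a trainable vector that is asked to predict the words it
contains (distributed bag of words, the doc2vec variant that ignores word
order).  Training minimises the negative-sampling objective

    -log σ(v_d · u_w) - Σ_{w'~noise} log σ(-v_d · u_w')

where v_d is the document vector, u_w the output vector of an observed
word, and noise words are drawn from the unigram distribution raised to
3/4.  Documents sharing vocabulary end up with high cosine similarity,
which is what the downstream UMAP -> HDBSCAN clustering consumes.

Deterministic for a fixed seed: single-threaded numpy, one RNG stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocess import TokenDoc

__all__ = ["Doc2VecModel", "embed_doc2vec"]


@dataclass
class Doc2VecModel:
    doc_vectors: np.ndarray       # (n_docs, dim)
    word_vectors: np.ndarray      # (V, dim) output embeddings
    vocabulary: list[str]
    doc_ids: list[str]
    dim: int
    epochs: int
    seed: int


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def embed_doc2vec(
    docs: list[TokenDoc],
    dim: int = 64,
    epochs: int = 30,
    seed: int = 0,
    negative: int = 5,
    lr: float = 0.05,
    lr_min: float = 1e-3,
    batch_size: int = 512,
) -> Doc2VecModel:
    """Train PV-DBOW document vectors on cleaned token documents."""
    if len(docs) < 10:
        raise ValueError("doc2vec needs at least 10 documents")
    rng = np.random.default_rng(seed)

    vocab: dict[str, int] = {}
    positions_d: list[int] = []
    positions_w: list[int] = []
    counts: list[int] = []
    for d, doc in enumerate(docs):
        for tok in doc.tokens:
            w = vocab.setdefault(tok, len(vocab))
            if w == len(counts):
                counts.append(0)
            counts[w] += 1
            positions_d.append(d)
            positions_w.append(w)
    if not vocab:
        raise ValueError("empty vocabulary")
    V = len(vocab)
    n_docs = len(docs)
    pos_d = np.asarray(positions_d, dtype=np.int64)
    pos_w = np.asarray(positions_w, dtype=np.int64)
    n_pos = pos_d.size

    noise = np.asarray(counts, dtype=float) ** 0.75
    noise /= noise.sum()

    D = (rng.random((n_docs, dim)) - 0.5) / dim
    W = np.zeros((V, dim))

    for epoch in range(epochs):
        cur_lr = lr - (lr - lr_min) * epoch / max(epochs - 1, 1)
        order = rng.permutation(n_pos)
        for start in range(0, n_pos, batch_size):
            sl = order[start : start + batch_size]
            d_idx = pos_d[sl]
            w_idx = pos_w[sl]
            B = d_idx.size
            dv = D[d_idx]                                   # (B, dim)
            # positive word
            wv = W[w_idx]                                   # (B, dim)
            g_pos = _sigmoid((dv * wv).sum(1)) - 1.0        # (B,)
            # negatives
            n_idx = rng.choice(V, size=(B, negative), p=noise)
            nv = W[n_idx]                                   # (B, neg, dim)
            g_neg = _sigmoid(np.einsum("bd,bnd->bn", dv, nv))  # (B, neg)

            grad_d = g_pos[:, None] * wv + np.einsum("bn,bnd->bd", g_neg, nv)
            grad_w = g_pos[:, None] * dv
            grad_n = g_neg[..., None] * dv[:, None, :]

            np.add.at(D, d_idx, -cur_lr * grad_d)
            np.add.at(W, w_idx, -cur_lr * grad_w)
            np.add.at(W, n_idx.ravel(), -cur_lr * grad_n.reshape(-1, dim))

    if not np.isfinite(D).all():
        raise FloatingPointError("doc2vec training diverged")
    inv_vocab = [None] * V
    for t, i in vocab.items():
        inv_vocab[i] = t
    return Doc2VecModel(
        doc_vectors=D,
        word_vectors=W,
        vocabulary=list(inv_vocab),
        doc_ids=[d.doc_id for d in docs],
        dim=dim,
        epochs=epochs,
        seed=seed,
    )
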