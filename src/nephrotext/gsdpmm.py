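"""Collapsed Gibbs sampler for the Dirichlet-process multinomial mixture.

Short diagnosis texts are modelled as draws from a mixture of multinomials
with a Dirichlet-process prior over mixture components: document d picks a
component z_d (Chinese-restaurant prior with concentration ``alpha``) and
its words are drawn i.i.d. from that component's term distribution, which
carries a symmetric Dirichlet(``beta``) prior.  Components are integrated
out, and the sampler sweeps over documents re-drawing z_d from its
conditional distribution given all other assignments.

With document d removed from the statistics, the conditional probability of
joining an occupied component k with m_k documents, term counts n_k(w) and
total count n_k is

    p(z_d = k) ∝ m_k * Π_w Γ(n_k(w)+c_d(w)+β)/Γ(n_k(w)+β)
                      / [ Γ(n_k+N_d+Vβ)/Γ(n_k+Vβ) ]

and the probability of opening a new component is the same expression with
m_k -> alpha and empty counts.  This favours few, vocabulary-coherent
components and infers the component count from the data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.special import gammaln

__all__ = ["GSDPMMResult", "gsdpmm_sample", "conditional_log_probs", "sample_dpmm_corpus"]


@dataclass
class GSDPMMResult:
    labels: np.ndarray          # per-doc component index, compact 0..K-1
    n_clusters: int
    alpha: float
    beta: float
    n_iter: int
    seed: int


def conditional_log_probs(
    doc_idx: np.ndarray,
    doc_cnt: np.ndarray,
    m: np.ndarray,
    nkw: np.ndarray,
    nk: np.ndarray,
    alpha: float,
    beta: float,
    vocab_size: int,
    allow_new: bool = True,
) -> np.ndarray:
    """Unnormalized log conditional over components for one held-out doc.

    Parameters are the sufficient statistics *excluding* the document:
    ``m`` (docs per component), ``nkw`` (component x vocab term counts,
    restricted here to the doc's nonzero columns ``doc_idx``), ``nk``
    (total words per component).  The last entry of the returned vector is
    the new-component option when ``allow_new``.
    """
    n_d = int(doc_cnt.sum())
    # occupied components
    word_term = (
        gammaln(nkw + doc_cnt[None, :] + beta) - gammaln(nkw + beta)
    ).sum(axis=1)
    len_term = gammaln(nk + vocab_size * beta) - gammaln(nk + n_d + vocab_size * beta)
    logp = np.log(m.astype(float)) + word_term + len_term
    if allow_new:
        new_word = (gammaln(doc_cnt + beta) - gammaln(np.full_like(doc_cnt, beta, dtype=float))).sum()
        new_len = gammaln(vocab_size * beta) - gammaln(n_d + vocab_size * beta)
        logp = np.append(logp, np.log(alpha) + new_word + new_len)
    return logp


def gsdpmm_sample(
    counts: sp.spmatrix,
    alpha: float = 1.0,
    beta: float = 0.05,
    k_max: int = 40,
    n_iter: int = 30,
    seed: int = 0,
) -> GSDPMMResult:
    """Run the collapsed Gibbs sampler; labels are taken from the last sweep.

    ``k_max`` caps the number of simultaneously occupied components (the
    initial assignment also uses ``k_max`` components); the Dirichlet
    process itself is unbounded, the cap keeps memory finite.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    X = sp.csr_matrix(counts)
    n_docs, V = X.shape
    rng = np.random.default_rng(seed)

    doc_idx = [X.indices[X.indptr[i]: X.indptr[i + 1]] for i in range(n_docs)]
    doc_cnt = [X.data[X.indptr[i]: X.indptr[i + 1]].astype(np.int64) for i in range(n_docs)]

    # statistics over a fixed-size table of component slots; occupied = m>0
    m = np.zeros(k_max, dtype=np.int64)
    nkw = np.zeros((k_max, V), dtype=np.int64)
    nk = np.zeros(k_max, dtype=np.int64)
    z = rng.integers(0, k_max, size=n_docs)
    for d in range(n_docs):
        k = z[d]
        m[k] += 1
        nkw[k, doc_idx[d]] += doc_cnt[d]
        nk[k] += doc_cnt[d].sum()

    order = np.arange(n_docs)
    for _ in range(n_iter):
        rng.shuffle(order)
        for d in order:
            k_old = z[d]
            m[k_old] -= 1
            nkw[k_old, doc_idx[d]] -= doc_cnt[d]
            nk[k_old] -= doc_cnt[d].sum()

            occ = np.flatnonzero(m > 0)
            free = np.flatnonzero(m == 0)
            allow_new = free.size > 0
            logp = conditional_log_probs(
                doc_idx[d],
                doc_cnt[d],
                m[occ],
                nkw[np.ix_(occ, doc_idx[d])],
                nk[occ],
                alpha,
                beta,
                V,
                allow_new=allow_new,
            )
            logp -= logp.max()
            p = np.exp(logp)
            p /= p.sum()
            choice = rng.choice(p.size, p=p)
            k_new = free[0] if (allow_new and choice == occ.size) else occ[choice]

            z[d] = k_new
            m[k_new] += 1
            nkw[k_new, doc_idx[d]] += doc_cnt[d]
            nk[k_new] += doc_cnt[d].sum()

    # compact relabel in order of first appearance
    remap: dict[int, int] = {}
    labels = np.empty(n_docs, dtype=np.int64)
    for d in range(n_docs):
        labels[d] = remap.setdefault(int(z[d]), len(remap))
    return GSDPMMResult(
        labels=labels,
        n_clusters=len(remap),
        alpha=alpha,
        beta=beta,
        n_iter=n_iter,
        seed=seed,
    )


def sample_dpmm_corpus(
    n_docs: int,
    vocab_size: int,
    doc_length: int,
    alpha: float,
    beta: float,
    seed: int,
) -> tuple[sp.csr_matrix, np.ndarray]:
    """Draw a corpus from the generative Dirichlet-process multinomial mixture.

    Components arise by the Chinese-restaurant process with concentration
    ``alpha``; each component's term distribution is Dirichlet(``beta``).
    Returns the count matrix and the true component labels — used to check
    that the sampler recovers the planted component count.
    """
    rng = np.random.default_rng(seed)
    labels = np.empty(n_docs, dtype=np.int64)
    sizes: list[int] = []
    for d in range(n_docs):
        probs = np.array(sizes + [alpha], dtype=float)
        probs /= probs.sum()
        k = rng.choice(len(probs), p=probs)
        if k == len(sizes):
            sizes.append(0)
        sizes[k] += 1
        labels[d] = k
    topics = rng.dirichlet(np.full(vocab_size, beta), size=len(sizes))
    rows = np.zeros((n_docs, vocab_size), dtype=np.int64)
    for d in range(n_docs):
        rows[d] = rng.multinomial(doc_length, topics[labels[d]])
    return sp.csr_matrix(rows), labels
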