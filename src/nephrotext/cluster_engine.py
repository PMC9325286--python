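"""Clustering backends for diagnosis-section documents.

Five paths produce a :class:`ClusterSet` over one corpus:

* ``kmeans``           — k-means on tf-idf vectors;
* ``lda``              — latent Dirichlet allocation on counts, label =
                         argmax topic;
* ``gsdpmm``           — collapsed Gibbs sampler for the Dirichlet-process
                         multinomial mixture (infers the cluster count);
* ``hdbscan``          — UMAP dimensionality reduction of tf-idf vectors
                         followed by density-based HDBSCAN, which may
                         reject documents as outliers (label -1);
* ``doc2vec-hdbscan``  — PV-DBOW document embeddings -> UMAP -> HDBSCAN,
                         the distributed-representation path.

k-means, LDA and GSDPMM label every document; only the HDBSCAN paths
produce outliers.  All backends are deterministic for a fixed seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from sklearn.cluster import HDBSCAN, KMeans
from sklearn.decomposition import LatentDirichletAllocation

from .doc2vec import embed_doc2vec
from .gsdpmm import gsdpmm_sample
from .preprocess import DocTermMatrix, TokenDoc

__all__ = [
    "ClusterSet",
    "EmbeddingMatrix",
    "ReducedEmbedding",
    "cluster_kmeans",
    "cluster_lda",
    "cluster_gsdpmm",
    "reduce_umap",
    "cluster_hdbscan",
    "select_k_elbow",
    "check_cluster_bounds",
    "save_clusterset",
    "load_clusterset",
    "load_external_embedding",
    "embed_corpus_doc2vec",
    "OUTLIER",
]

OUTLIER = -1


@dataclass
class ClusterSet:
    """Per-document labels in {-1, 0..K-1}; -1 marks outliers."""

    labels: np.ndarray
    method: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    doc_ids: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.min(initial=0) < -1:
            raise ValueError("labels below -1 are not allowed")

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels[self.labels >= 0]).size)

    @property
    def kept_mask(self) -> np.ndarray:
        return self.labels >= 0

    @property
    def corpus_size_kept(self) -> int:
        return int(self.kept_mask.sum())


@dataclass
class EmbeddingMatrix:
    """Dense document embeddings (trained here or ingested externally)."""

    matrix: np.ndarray
    source: str  # "doc2vec" or "external"
    doc_ids: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] < 1:
            raise ValueError("embedding must be 2-D with d > 0")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embedding contains non-finite values")


@dataclass
class ReducedEmbedding:
    """Low-dimensional projection of a document representation."""

    matrix: np.ndarray
    params: dict
    seed: int

    def __post_init__(self) -> None:
        if self.matrix.shape[1] < 2:
            raise ValueError("reduced dimension must be >= 2")


def _compact_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel nonnegative labels to a dense 0..K-1 range, keeping -1."""
    out = np.full(raw.shape, OUTLIER, dtype=np.int64)
    for new, old in enumerate(np.unique(raw[raw >= 0])):
        out[raw == old] = new
    return out


def cluster_kmeans(X: DocTermMatrix, k: int, seed: int = 0, n_init: int = 20) -> ClusterSet:
    """k-means on the document-term matrix; every document is labelled."""
    n_docs = X.shape[0]
    if not 2 <= k <= n_docs:
        raise ValueError(f"k must be in [2, {n_docs}], got {k}")
    km = KMeans(n_clusters=k, random_state=seed, n_init=n_init)
    labels = km.fit_predict(X.matrix)
    return ClusterSet(
        labels=_compact_labels(labels),
        method="kmeans",
        params={"k": k, "n_init": n_init},
        seed=seed,
        doc_ids=list(X.doc_ids),
    )


class _WarmStartLDA(LatentDirichletAllocation):
    """LDA whose variational topic-word parameters can be seeded externally
    (e.g. from a k-means partition) instead of pure random initialization."""

    warm_components: Optional[np.ndarray] = None

    def _init_latent_vars(self, n_features, dtype=np.float64):  # noqa: D102
        super()._init_latent_vars(n_features, dtype=dtype)
        if self.warm_components is not None:
            from sklearn.decomposition._lda import _dirichlet_expectation_2d

            self.components_ = np.asarray(self.warm_components, dtype=dtype)
            # keep the cached expectation consistent with the new components
            self.exp_dirichlet_component_ = np.exp(
                _dirichlet_expectation_2d(self.components_)
            )


def cluster_lda(
    X: DocTermMatrix, k: int, seed: int = 0, max_iter: int = 50, n_init: int = 8
) -> ClusterSet:
    """LDA topic model on counts; document label = most probable topic.

    Variational EM is prone to local optima in which one topic covers two
    groups.  The fit is therefore restarted ``n_init`` times (random seeds
    ``seed`` .. ``seed + n_init - 1``) plus one restart whose topic-word
    parameters are warm-started from a k-means partition of the L2-normalised
    count rows; the solution with the highest evidence lower bound wins.
    """
    if X.mode != "count":
        raise ValueError("LDA requires a count-mode matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = sp.csr_matrix(X.matrix, dtype=float)

    fits: list[LatentDirichletAllocation] = [
        LatentDirichletAllocation(n_components=k, random_state=seed + i,
                                  max_iter=max_iter)
        for i in range(n_init)
    ]
    if 2 <= k <= counts.shape[0]:
        from sklearn.preprocessing import normalize

        km = KMeans(n_clusters=k, random_state=seed, n_init=5)
        part = km.fit_predict(normalize(counts))
        warm = np.vstack([
            np.asarray(counts[part == c].sum(axis=0)).ravel() + 1.0 / k
            for c in range(k)
        ])
        warm_lda = _WarmStartLDA(n_components=k, random_state=seed,
                                 max_iter=max_iter)
        warm_lda.warm_components = warm
        fits.append(warm_lda)

    best_theta, best_score = None, -np.inf
    for lda in fits:
        theta = lda.fit_transform(X.matrix)
        score = lda.score(X.matrix)
        if score > best_score:
            best_score, best_theta = score, theta
    labels = np.argmax(best_theta, axis=1)  # argmax breaks ties toward lower index
    return ClusterSet(
        labels=_compact_labels(labels),
        method="lda",
        params={"k": k, "max_iter": max_iter, "n_init": n_init},
        seed=seed,
        doc_ids=list(X.doc_ids),
    )


def cluster_gsdpmm(
    X: DocTermMatrix,
    alpha: float = 1.0,
    beta: float = 0.05,
    k_max: int = 40,
    n_iter: int = 30,
    seed: int = 0,
) -> ClusterSet:
    """Dirichlet-process multinomial mixture; cluster count is inferred."""
    if X.mode != "count":
        raise ValueError("GSDPMM requires a count-mode matrix")
    res = gsdpmm_sample(X.matrix, alpha=alpha, beta=beta, k_max=k_max, n_iter=n_iter, seed=seed)
    return ClusterSet(
        labels=res.labels,
        method="gsdpmm",
        params={"alpha": alpha, "beta": beta, "k_max": k_max, "n_iter": n_iter},
        seed=seed,
        doc_ids=list(X.doc_ids),
    )


def reduce_umap(
    X,
    d: int = 5,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
) -> ReducedEmbedding:
    """UMAP projection used before density-based clustering and for plots."""
    import umap  # deferred: numba compilation is expensive at import time

    mat = X.matrix if hasattr(X, "matrix") else X
    n_docs = mat.shape[0]
    if n_docs <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} documents, got {n_docs}")
    reducer = umap.UMAP(
        n_components=d,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        emb = reducer.fit_transform(mat)
    return ReducedEmbedding(
        matrix=np.asarray(emb, dtype=float),
        params={"d": d, "n_neighbors": n_neighbors, "min_dist": min_dist},
        seed=seed,
    )


def cluster_hdbscan(
    E: ReducedEmbedding,
    min_cluster_size: int = 10,
    doc_ids: Optional[list[str]] = None,
    method: str = "hdbscan",
) -> ClusterSet:
    """Density-based clustering with outlier rejection (label -1)."""
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    labels = HDBSCAN(min_cluster_size=min_cluster_size).fit_predict(E.matrix)
    return ClusterSet(
        labels=_compact_labels(labels),
        method=method,
        params={"min_cluster_size": min_cluster_size, **E.params},
        seed=E.seed,
        doc_ids=doc_ids,
    )


def select_k_elbow(
    X: DocTermMatrix,
    k_range: Sequence[int],
    seed: int = 0,
    inertias: Optional[Sequence[float]] = None,
) -> int:
    """Elbow-based choice of k from the k-means inertia curve.

    The elbow is the k maximising the vertical distance between the
    (normalised) inertia curve and the chord joining its endpoints; ties go
    to the smaller k.  A flat curve has no elbow and falls back to the
    smallest k with a warning.  ``inertias`` may be supplied directly (one
    value per k) to apply the rule to any backend's objective curve.
    """
    ks = np.asarray(sorted(k_range))
    if ks.size < 3:
        raise ValueError("k_range needs at least 3 values")
    if inertias is None:
        vals = []
        for k in ks:
            km = KMeans(n_clusters=int(k), random_state=seed, n_init=5)
            km.fit(X.matrix)
            vals.append(km.inertia_)
        inertias = vals
    y = np.asarray(inertias, dtype=float)
    if y.size != ks.size:
        raise ValueError("one inertia value per k is required")
    span = y[0] - y[-1]
    if abs(span) < 1e-12 * max(abs(y[0]), 1.0):
        warnings.warn("flat inertia curve: no elbow, returning smallest k")
        return int(ks[0])
    # normalise both axes to [0,1]; chord is then the identity line
    xn = (ks - ks[0]) / (ks[-1] - ks[0])
    yn = (y[0] - y) / span
    dist = yn - xn
    return int(ks[int(np.argmax(dist))])  # argmax takes the first (smallest k) tie


def check_cluster_bounds(cs: ClusterSet, lo: int = 10, hi: int = 20) -> list[str]:
    """Warn (never fail) when the cluster count leaves the target band."""
    k = cs.n_clusters
    if k < lo:
        return [f"{cs.method}: {k} clusters is below the target minimum of {lo}"]
    if k > hi:
        return [f"{cs.method}: {k} clusters exceeds the target maximum of {hi}"]
    return []


def save_clusterset(cs: ClusterSet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec = {
        "method": cs.method,
        "params": cs.params,
        "seed": cs.seed,
        "labels": cs.labels.tolist(),
        "doc_ids": cs.doc_ids,
    }
    path.write_text(json.dumps(rec, sort_keys=True) + "\n", encoding="utf-8")


def load_clusterset(path: str | Path) -> ClusterSet:
    rec = json.loads(Path(path).read_text(encoding="utf-8"))
    return ClusterSet(
        labels=np.asarray(rec["labels"], dtype=np.int64),
        method=rec["method"],
        params=rec["params"],
        seed=rec["seed"],
        doc_ids=rec["doc_ids"],
    )


def load_external_embedding(path: str | Path, doc_ids_path: str | Path) -> EmbeddingMatrix:
    """Ingest an externally produced dense embedding matrix.

    ``path`` is a whitespace-delimited text matrix (one row per document) or
    an MTX file; ``doc_ids_path`` is the one-id-per-line sidecar.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        raw = mmread(str(path))
        mat = np.asarray(raw.todense()) if sp.issparse(raw) else np.asarray(raw)
    else:
        mat = np.loadtxt(path)
    ids = [
        l for l in Path(doc_ids_path).read_text(encoding="utf-8").split("\n") if l
    ]
    if mat.shape[0] != len(ids):
        raise ValueError("embedding rows and doc-id sidecar disagree")
    return EmbeddingMatrix(matrix=mat, source="external", doc_ids=ids)


def embed_corpus_doc2vec(
    docs: list[TokenDoc], dim: int = 64, epochs: int = 30, seed: int = 0
) -> EmbeddingMatrix:
    """Train PV-DBOW vectors and wrap them for the clustering path."""
    model = embed_doc2vec(docs, dim=dim, epochs=epochs, seed=seed)
    return EmbeddingMatrix(
        matrix=model.doc_vectors, source="doc2vec", doc_ids=model.doc_ids
    )
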