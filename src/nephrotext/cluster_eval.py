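"""Cluster-set quality metrics, 2-D projections and author-confound checks.

Three complementary metrics score a cluster-set without ground truth:

* **silhouette** (s-score) — geometric separation of the clusters in the
  representation the clusterer consumed; favours convex clusters.
* **relative document entropy** — mean KL divergence between a document's
  term-frequency distribution and its cluster's pooled distribution,
  averaged within clusters and then across clusters.  Low values mean
  vocabulary-homogeneous clusters.
* **cls accuracy** — how well a linear SVM can re-predict the cluster label
  from the diagnosis text (stratified 10-fold cross-validation); shape-free
  measure of how learnable the partition is.

Outlier documents (label -1) are excluded from every metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.decomposition import PCA
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import silhouette_score
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .cluster_engine import ClusterSet, reduce_umap
from .preprocess import DocTermMatrix, TokenDoc

__all__ = [
    "ClusterSetMetrics",
    "AuthorConfoundReport",
    "silhouette",
    "relative_entropy",
    "cls_accuracy",
    "evaluate_clusterset",
    "project_2d",
    "author_confound",
]


@dataclass
class ClusterSetMetrics:
    """One scorecard row for a cluster-set."""

    method: str
    s_score: float
    cls_accuracy: float
    rel_entropy: float
    n_clusters: int
    corpus_size: int
    representation: str = "tfidf"  # space in which the silhouette was taken

    def __post_init__(self) -> None:
        if not -1.0 <= self.s_score <= 1.0:
            raise ValueError("silhouette out of [-1, 1]")
        if not 0.0 <= self.cls_accuracy <= 1.0:
            raise ValueError("cls accuracy out of [0, 1]")
        if self.rel_entropy < -1e-12:
            raise ValueError("relative entropy must be nonnegative")


@dataclass
class AuthorConfoundReport:
    contingency: np.ndarray      # clusters x authors
    association: float           # Cramér's V in [0, 1]
    cluster_ids: list[int]
    author_codes: list[str]


def silhouette(X, cs: ClusterSet) -> float:
    """Mean silhouette coefficient over non-outlier documents (Euclidean)."""
    mat = X.matrix if hasattr(X, "matrix") else np.asarray(X)
    kept = cs.kept_mask
    labels = cs.labels[kept]
    if np.unique(labels).size < 2:
        raise ValueError("silhouette needs at least 2 clusters")
    sub = mat[kept]
    if sp.issparse(sub):
        sub = np.asarray(sub.todense())
    return float(silhouette_score(sub, labels, metric="euclidean"))


def relative_entropy(C: DocTermMatrix, cs: ClusterSet) -> float:
    """Mean per-cluster mean KL(document ‖ cluster pool), natural log.

    For each non-outlier document i in cluster j, p_i is document i's term
    counts normalised over the cluster-j vocabulary (terms with nonzero
    pooled count) and q_j is the pooled cluster distribution normalised the
    same way.  The pool includes document i, so q_j > 0 wherever p_i > 0
    and the divergence is finite without smoothing.  Cluster means are then
    averaged unweighted across clusters.
    """
    if C.mode != "count":
        raise ValueError("relative entropy requires a count-mode matrix")
    X = sp.csr_matrix(C.matrix)
    cluster_means: list[float] = []
    for j in np.unique(cs.labels[cs.labels >= 0]):
        rows = np.flatnonzero(cs.labels == j)
        if rows.size == 0:
            raise ValueError(f"cluster {j} is empty")
        sub = np.asarray(X[rows].todense(), dtype=float)
        pooled = sub.sum(axis=0)
        support = pooled > 0
        q = pooled[support] / pooled[support].sum()
        kls = []
        for r in range(sub.shape[0]):
            p_row = sub[r, support]
            total = p_row.sum()
            if total == 0:
                kls.append(0.0)
                continue
            p = p_row / total
            nz = p > 0
            kls.append(float(np.sum(p[nz] * np.log(p[nz] / q[nz]))))
        cluster_means.append(float(np.mean(kls)))
    if not cluster_means:
        raise ValueError("cluster-set has no clusters")
    return float(np.mean(cluster_means))


def cls_accuracy(
    diagnosis_texts: list[str] | list[TokenDoc],
    cs: ClusterSet,
    seed: int = 0,
    n_folds: int = 10,
) -> float:
    """Accuracy of a linear SVM predicting cluster labels from diagnoses.

    The SVM consumes tf-idf of the diagnosis sections; accuracy is pooled
    over stratified cross-validation folds on non-outlier documents.
    Clusters smaller than the fold count reduce the fold count (with a
    warning) rather than being dropped.
    """
    texts = [
        " ".join(t.tokens) if isinstance(t, TokenDoc) else t for t in diagnosis_texts
    ]
    kept = np.flatnonzero(cs.kept_mask)
    y = cs.labels[kept]
    if np.unique(y).size < 2:
        raise ValueError("cls accuracy needs at least 2 clusters")
    texts = [texts[i] for i in kept]
    min_class = np.bincount(y).min() if np.bincount(y).size else 0
    folds = n_folds
    if min_class < folds:
        folds = max(2, int(min_class))
        warnings.warn(
            f"smallest cluster has {min_class} docs; reducing folds to {folds}"
        )
    vec = TfidfVectorizer(lowercase=False, token_pattern=r"\S+")
    correct = 0
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train, test in skf.split(texts, y):
        Xtr = vec.fit_transform([texts[i] for i in train])
        Xte = vec.transform([texts[i] for i in test])
        clf = LinearSVC(random_state=seed)
        clf.fit(Xtr, y[train])
        correct += int((clf.predict(Xte) == y[test]).sum())
    return correct / y.size


def evaluate_clusterset(
    diagnosis_docs: list[TokenDoc],
    counts: DocTermMatrix,
    representation,
    cs: ClusterSet,
    seed: int = 0,
    representation_name: str = "tfidf",
) -> ClusterSetMetrics:
    """Assemble the full scorecard row for one cluster-set.

    ``representation`` is whatever matrix the clusterer consumed (tf-idf for
    bag-of-words backends, the reduced embedding for the HDBSCAN paths);
    the silhouette is computed there and the space is recorded.
    """
    return ClusterSetMetrics(
        method=cs.method,
        s_score=silhouette(representation, cs),
        cls_accuracy=cls_accuracy(diagnosis_docs, cs, seed=seed),
        rel_entropy=relative_entropy(counts, cs),
        n_clusters=cs.n_clusters,
        corpus_size=cs.corpus_size_kept,
        representation=representation_name,
    )


def project_2d(X, method: str = "umap", seed: int = 0) -> np.ndarray:
    """2-D coordinates for plotting a cluster-set (UMAP or PCA)."""
    mat = X.matrix if hasattr(X, "matrix") else np.asarray(X)
    if mat.shape[0] < 3:
        raise ValueError("need at least 3 documents to project")
    if method == "pca":
        dense = np.asarray(mat.todense()) if sp.issparse(mat) else mat
        return PCA(n_components=2, random_state=seed).fit_transform(dense)
    if method == "umap":
        return reduce_umap(mat, d=2, seed=seed).matrix
    raise ValueError(f"unknown projection method {method!r}")


def author_confound(cs: ClusterSet, authors: list[str | None]) -> AuthorConfoundReport:
    """Cluster x author contingency table and Cramér's V association.

    Quantifies whether clusters align with report authorship (style
    confound) rather than with diagnostic content.  Documents without an
    author code are skipped with a warning.
    """
    kept = cs.kept_mask
    rows = [
        (int(cs.labels[i]), authors[i]) for i in np.flatnonzero(kept)
    ]
    known = [(c, a) for c, a in rows if a is not None]
    if len(known) < len(rows):
        warnings.warn(
            f"{len(rows) - len(known)} kept documents lack author codes; "
            "association computed on the rest"
        )
    if not known:
        raise ValueError("no author codes available")
    cluster_ids = sorted({c for c, _ in known})
    author_codes = sorted({a for _, a in known})
    table = np.zeros((len(cluster_ids), len(author_codes)), dtype=np.int64)
    ci = {c: i for i, c in enumerate(cluster_ids)}
    ai = {a: i for i, a in enumerate(author_codes)}
    for c, a in known:
        table[ci[c], ai[a]] += 1
    n = table.sum()
    if min(table.shape) < 2:
        v = 0.0
    else:
        row = table.sum(1, keepdims=True)
        col = table.sum(0, keepdims=True)
        expected = row @ col / n
        chi2 = float(((table - expected) ** 2 / np.where(expected > 0, expected, 1)).sum())
        v = float(np.sqrt(chi2 / (n * (min(table.shape) - 1))))
    return AuthorConfoundReport(
        contingency=table,
        association=min(v, 1.0),
        cluster_ids=cluster_ids,
        author_codes=author_codes,
    )
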