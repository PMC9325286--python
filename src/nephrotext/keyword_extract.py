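"""Per-cluster keyword extraction and expert cluster naming.

Two methodologically different extractors produce ranked top-N term lists
per cluster:

* **tf-idf** — every cluster is pooled into one pseudo-document; tf-idf
  across pseudo-documents surfaces the terms whose frequencies set one
  cluster apart from the rest.
* **SVM weights** — a linear one-vs-rest SVM is trained to predict the
  cluster from the document's tf-idf vector; the analysis is restricted to
  the documents the model predicts correctly (re-fit on that subset), and
  each cluster's keywords are the features with the largest positive
  weights for its decision function.

The resulting tables are what domain experts annotate with diagnostic
group names ("systemic lupus erythematosus", "IgA nephritis", ...); the
naming file may legitimately leave clusters unnamed.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.feature_extraction.text import TfidfTransformer
from sklearn.svm import LinearSVC

from .cluster_engine import ClusterSet
from .preprocess import DocTermMatrix

__all__ = [
    "KeywordTable",
    "ClusterNaming",
    "keywords_tfidf",
    "keywords_svm",
    "attach_naming",
    "save_keyword_table",
]


@dataclass
class KeywordTable:
    method: str  # "tfidf" or "svm"
    per_cluster: dict[int, list[tuple[str, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for c, pairs in self.per_cluster.items():
            scores = [s for _, s in pairs]
            if any(a < b for a, b in zip(scores, scores[1:])):
                raise ValueError(f"cluster {c}: scores must be nonincreasing")
            terms = [t for t, _ in pairs]
            if len(terms) != len(set(terms)):
                raise ValueError(f"cluster {c}: duplicate terms")

    def terms(self, cluster: int) -> list[str]:
        return [t for t, _ in self.per_cluster.get(cluster, [])]


@dataclass
class ClusterNaming:
    names: dict[int, tuple[str, str]]  # cluster -> (name, strength)
    clusters: list[int]                # all clusters of the cluster-set

    @property
    def unnamed(self) -> list[int]:
        return [c for c in self.clusters if c not in self.names]


def _top_terms(
    scores: np.ndarray, vocabulary: list[str], top_n: int
) -> list[tuple[str, float]]:
    # sort by descending score, ties broken lexicographically
    order = sorted(range(len(vocabulary)), key=lambda i: (-scores[i], vocabulary[i]))
    out = [(vocabulary[i], float(scores[i])) for i in order[:top_n]]
    return [(t, s) for t, s in out if s > 0] or out[:1]


def keywords_tfidf(
    C: DocTermMatrix, cs: ClusterSet, top_n: int = 10
) -> KeywordTable:
    """Top terms per cluster by tf-idf over cluster pseudo-documents."""
    if C.mode != "count":
        raise ValueError("keyword tf-idf starts from a count matrix")
    clusters = np.unique(cs.labels[cs.labels >= 0])
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters (idf degenerate otherwise)")
    X = sp.csr_matrix(C.matrix)
    pooled = np.vstack(
        [np.asarray(X[cs.labels == c].sum(axis=0)).ravel() for c in clusters]
    )
    tfidf = TfidfTransformer(norm="l2", smooth_idf=True).fit_transform(
        sp.csr_matrix(pooled)
    )
    tfidf = np.asarray(tfidf.todense())
    table = {
        int(c): _top_terms(tfidf[row], C.vocabulary, top_n)
        for row, c in enumerate(clusters)
    }
    return KeywordTable(method="tfidf", per_cluster=table)


def keywords_svm(
    X: DocTermMatrix, cs: ClusterSet, top_n: int = 10, seed: int = 0
) -> KeywordTable:
    """Top positive SVM weights per cluster, restricted to documents the
    model predicts correctly.

    A linear one-vs-rest SVM is first fit on all kept documents; the
    correctly predicted subset is identified and the SVM re-fit on it; each
    cluster's keywords are the features with the largest positive weight in
    its one-vs-rest decision function.
    """
    kept = np.flatnonzero(cs.kept_mask)
    y = cs.labels[kept]
    clusters = np.unique(y)
    if clusters.size < 2:
        raise ValueError("need at least 2 clusters")
    M = sp.csr_matrix(X.matrix)[kept]
    clf = LinearSVC(random_state=seed)
    clf.fit(M, y)
    correct = clf.predict(M) == y
    table: dict[int, list[tuple[str, float]]] = {}
    refit = LinearSVC(random_state=seed)
    sub_y = y[correct]
    present = np.unique(sub_y)
    if present.size >= 2:
        refit.fit(M[correct], sub_y)
        coef = refit.coef_ if refit.coef_.shape[0] > 1 else np.vstack(
            [-refit.coef_[0], refit.coef_[0]]
        )
        for row, c in enumerate(present):
            table[int(c)] = _top_terms(coef[row], X.vocabulary, top_n)
    for c in clusters:
        if int(c) not in table:
            warnings.warn(f"cluster {c}: no correctly predicted documents; empty list")
            table[int(c)] = []
    return KeywordTable(method="svm", per_cluster=table)


def attach_naming(kt: KeywordTable, annotation_file: str | Path) -> ClusterNaming:
    """Join a TSV annotation file (cluster, name, strength) to the table.

    Unnamed clusters are allowed; annotations for unknown clusters or
    duplicate cluster indices are validation errors.
    """
    clusters = sorted(kt.per_cluster)
    names: dict[int, tuple[str, str]] = {}
    with Path(annotation_file).open(encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            c = int(row[0])
            if c not in kt.per_cluster:
                raise ValueError(f"annotation references unknown cluster {c}")
            if c in names:
                raise ValueError(f"duplicate annotation for cluster {c}")
            name = row[1].strip() if len(row) > 1 else ""
            strength = row[2].strip() if len(row) > 2 else "strong"
            if strength not in ("strong", "weak"):
                raise ValueError(f"cluster {c}: unknown strength {strength!r}")
            if name:
                names[c] = (name, strength)
    return ClusterNaming(names=names, clusters=clusters)


def save_keyword_table(kt: KeywordTable, path: str | Path) -> None:
    """Export as TSV: cluster, rank, term, score, method."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["cluster", "rank", "term", "score", "method"])
        for c in sorted(kt.per_cluster):
            for rank, (term, score) in enumerate(kt.per_cluster[c], start=1):
                w.writerow([c, rank, term, f"{score:.6f}", kt.method])
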