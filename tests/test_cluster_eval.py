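"""Cluster metrics against brute-force oracles, projections, confound."""

import numpy as np
import pytest

from nephrotext.cluster_engine import ClusterSet
from nephrotext.cluster_eval import (author_confound, cls_accuracy,
                                     evaluate_clusterset, project_2d,
                                     relative_entropy, silhouette)
from nephrotext.preprocess import TokenDoc, vectorize
from tests.conftest import make_token_docs


def brute_silhouette(X, labels):
    """O(n^2) pairwise silhouette, written independently of sklearn."""
    X = np.asarray(X, dtype=float)
    n = len(labels)
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    svals = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            svals.append(0.0)
            continue
        a = np.mean([d[i, j] for j in own])
        b = min(np.mean([d[i, j] for j in range(n) if labels[j] == c])
                for c in set(labels) if c != labels[i])
        svals.append((b - a) / max(a, b))
    return float(np.mean(svals))


def brute_relative_entropy(count_rows, labels):
    """Explicit sum p log(p/q) per document over the cluster vocabulary."""
    cluster_means = []
    for c in sorted(set(l for l in labels if l >= 0)):
        rows = [count_rows[i] for i in range(len(labels)) if labels[i] == c]
        pooled = np.sum(rows, axis=0)
        support = pooled > 0
        q = pooled[support] / pooled[support].sum()
        kls = []
        for r in rows:
            p = r[support] / r[support].sum()
            kl = sum(pi * np.log(pi / qi) for pi, qi in zip(p, q) if pi > 0)
            kls.append(kl)
        cluster_means.append(np.mean(kls))
    return float(np.mean(cluster_means))


class TestSilhouette:
    def test_duplicated_far_clusters_score_one(self):
        X = np.array([[0.0, 0.0]] * 4 + [[100.0, 0.0]] * 4)
        cs = ClusterSet(labels=np.repeat([0, 1], 4), method="m")
        assert silhouette(X, cs) == pytest.approx(1.0)

    def test_matches_pairwise_oracle_on_planar_points(self):
        X = np.array([[0, 0], [1, 0], [0, 1], [5, 5], [6, 5], [5, 6]], dtype=float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        cs = ClusterSet(labels=labels, method="m")
        assert silhouette(X, cs) == pytest.approx(brute_silhouette(X, labels),
                                                  abs=1e-10)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            silhouette(np.zeros((4, 2)), ClusterSet(labels=np.zeros(4, int),
                                                    method="m"))

    def test_outliers_ignored(self):
        X = np.array([[0, 0], [0, 1], [9, 9], [9, 8], [50, 50]], dtype=float)
        base = ClusterSet(labels=np.array([0, 0, 1, 1, -1]), method="m")
        no_out = ClusterSet(labels=np.array([0, 0, 1, 1]), method="m")
        assert silhouette(X, base) == pytest.approx(silhouette(X[:4], no_out))


class TestRelativeEntropy:
    def _dtm(self, docs):
        return vectorize(docs, "count")

    def test_identical_documents_zero(self):
        docs = [TokenDoc(str(i), ("a", "b", "b")) for i in range(6)]
        cs = ClusterSet(labels=np.repeat([0, 1], 3), method="m")
        assert relative_entropy(self._dtm(docs), cs) == pytest.approx(0.0, abs=1e-12)

    def test_singleton_cluster_contributes_zero(self):
        docs = [TokenDoc("0", ("a", "a")), TokenDoc("1", ("b", "c"))]
        cs = ClusterSet(labels=np.array([0, 1]), method="m")
        assert relative_entropy(self._dtm(docs), cs) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_on_four_doc_toy(self):
        docs = [TokenDoc("0", ("a", "a", "b")), TokenDoc("1", ("a", "b", "b", "b")),
                TokenDoc("2", ("c", "d")), TokenDoc("3", ("c", "c", "d", "e"))]
        labels = np.array([0, 0, 1, 1])
        dtm = self._dtm(docs)
        rows = [np.asarray(dtm.matrix[i].todense()).ravel() for i in range(4)]
        oracle = brute_relative_entropy(rows, labels)
        got = relative_entropy(dtm, ClusterSet(labels=labels, method="m"))
        assert got == pytest.approx(oracle, abs=1e-10)
        assert got > 0  # distinct distributions within clusters

    def test_outlier_documents_do_not_change_value(self):
        docs = [TokenDoc("0", ("a", "b")), TokenDoc("1", ("a", "a", "b")),
                TokenDoc("2", ("z", "q", "r"))]
        with_out = ClusterSet(labels=np.array([0, 0, -1]), method="m")
        without = ClusterSet(labels=np.array([0, 0]), method="m")
        v1 = relative_entropy(self._dtm(docs), with_out)
        v2 = relative_entropy(self._dtm(docs[:2]), without)
        assert v1 == pytest.approx(v2, abs=1e-12)

    def test_tfidf_input_rejected(self):
        docs = [TokenDoc("0", ("a", "b")), TokenDoc("1", ("a", "c"))]
        with pytest.raises(ValueError):
            relative_entropy(vectorize(docs, "tfidf"),
                             ClusterSet(labels=np.array([0, 1]), method="m"))


class TestClsAccuracy:
    def test_disjoint_vocabularies_near_perfect(self):
        docs = make_token_docs([0] * 20 + [1] * 20, seed=1)
        cs = ClusterSet(labels=np.repeat([0, 1], 20), method="m")
        assert cls_accuracy(docs, cs, seed=0) >= 0.99

    def test_single_cluster_rejected(self):
        docs = make_token_docs([0] * 10)
        with pytest.raises(ValueError):
            cls_accuracy(docs, ClusterSet(labels=np.zeros(10, int), method="m"))

    def test_seed_deterministic(self):
        docs = make_token_docs([0] * 15 + [1] * 15, seed=2)
        cs = ClusterSet(labels=np.repeat([0, 1], 15), method="m")
        assert cls_accuracy(docs, cs, seed=7) == cls_accuracy(docs, cs, seed=7)


class TestProjection:
    def test_pca_collinear_second_component_zero(self):
        t = np.linspace(0, 1, 8)
        X = np.column_stack([t, 2 * t, -t])
        coords = project_2d(X, method="pca")
        assert np.var(coords[:, 1]) == pytest.approx(0.0, abs=1e-20)

    def test_pca_matches_eigendecomposition_oracle(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        coords = project_2d(X, method="pca")
        Xc = X - X.mean(0)
        evals, evecs = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        order = np.argsort(evals)[::-1]
        oracle = Xc @ evecs[:, order[:2]]
        for j in range(2):  # eigenvector sign is arbitrary
            assert (np.allclose(coords[:, j], oracle[:, j], atol=1e-8)
                    or np.allclose(coords[:, j], -oracle[:, j], atol=1e-8))

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            project_2d(np.zeros((2, 3)), method="pca")


class TestAuthorConfound:
    def test_perfect_association(self):
        labels = np.repeat([0, 1, 2], 20)
        authors = [f"author_{l}" for l in labels]
        rep = author_confound(ClusterSet(labels=labels, method="m"), authors)
        assert rep.association == pytest.approx(1.0)
        assert rep.contingency.sum() == 60

    def test_independent_assignment_near_zero(self):
        """Mean association over independent simulations stays below 0.1."""
        rng = np.random.default_rng(11)
        vals = []
        for _ in range(10):
            labels = rng.integers(0, 4, size=500)
            authors = [f"author_{a}" for a in rng.integers(0, 3, size=500)]
            rep = author_confound(ClusterSet(labels=labels, method="m"), authors)
            vals.append(rep.association)
        assert np.mean(vals) < 0.1

    def test_missing_authors_partial_with_warning(self):
        labels = np.array([0, 0, 1, 1])
        with pytest.warns(UserWarning, match="lack author"):
            rep = author_confound(ClusterSet(labels=labels, method="m"),
                                  ["a", None, "b", "b"])
        assert rep.contingency.sum() == 3


class TestEvaluateClusterset:
    def test_perfect_partition_scores_cleanly(self, separable_corpus):
        _, corpus, truth, diag, _ = separable_corpus
        counts = vectorize(diag, "count")
        tfidf = vectorize(diag, "tfidf")
        cs = ClusterSet(labels=truth.group, method="truth",
                        doc_ids=[r.id for r in corpus.reports])
        m = evaluate_clusterset(diag, counts, tfidf, cs, seed=0)
        assert m.cls_accuracy >= 0.99
        assert m.s_score > 0.3       # tf-idf sampling noise keeps it below 1
        assert m.n_clusters == 4 and m.corpus_size == len(corpus.reports)
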