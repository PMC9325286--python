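"""Description-based classification: CV protocol, metrics, comparisons."""

import numpy as np
import pytest
import scipy.sparse as sp

from nephrotext.classify import (ClassifierSpec, _pooled_report, build_sklearn,
                                 compare_classifiers, support_vs_f1,
                                 train_predict_cv)
from nephrotext.cluster_engine import ClusterSet
from nephrotext.preprocess import TokenDoc
from tests.conftest import make_token_docs


@pytest.fixture(scope="module")
def separable_two_class():
    docs = make_token_docs([0] * 20 + [1] * 20, seed=5)
    cs = ClusterSet(labels=np.repeat([0, 1], 20), method="truth")
    return docs, cs


class TestTrainPredictCV:
    def test_separable_corpus_perfect_scores(self, separable_two_class):
        docs, cs = separable_two_class
        rep = train_predict_cv(docs, cs, ClassifierSpec("sgd_svm", seed=0))
        assert rep.f1_macro == 1.0 and rep.kappa == 1.0
        assert np.trace(rep.confusion) == 40

    def test_confusion_conserves_documents(self, separable_two_class):
        docs, cs = separable_two_class
        rep = train_predict_cv(docs, cs, ClassifierSpec("logreg", seed=0))
        assert rep.confusion.sum() == cs.corpus_size_kept
        assert sum(s for _, _, s in rep.per_class) == cs.corpus_size_kept

    def test_outliers_excluded(self):
        docs = make_token_docs([0] * 10 + [1] * 10 + [2] * 3, seed=6)
        labels = np.array([0] * 10 + [1] * 10 + [-1] * 3)
        rep = train_predict_cv(docs, ClusterSet(labels=labels, method="m"),
                               ClassifierSpec("multinomial_nb", seed=0))
        assert rep.confusion.sum() == 20

    def test_singleton_class_rejected_by_name(self):
        docs = make_token_docs([0] * 5 + [1] * 5 + [2], seed=0)
        labels = np.array([0] * 5 + [1] * 5 + [2])
        with pytest.raises(ValueError, match=r"\[2\]"):
            train_predict_cv(docs, ClusterSet(labels=labels, method="m"),
                             ClassifierSpec("sgd_svm", seed=0))

    def test_unknown_spec_rejected(self):
        with pytest.raises(ValueError, match="unknown classifier"):
            ClassifierSpec("bert", seed=0)

    def test_neural_spec_on_separable_toy(self, separable_two_class):
        docs, cs = separable_two_class
        spec = ClassifierSpec("cnn_embed", seed=0,
                              hyperparams=(("epochs", 25),))
        rep = train_predict_cv(docs, cs, spec, n_folds=3)
        assert rep.f1_weighted >= 0.9


class TestMultinomialNB:
    def test_posterior_matches_hand_computed_bayes(self):
        """4-doc 2-class count toy with Laplace smoothing (alpha=1)."""
        X = sp.csr_matrix(np.array([[2, 0], [1, 1], [0, 2], [0, 1]]))
        y = np.array([0, 0, 1, 1])
        clf = build_sklearn(ClassifierSpec("multinomial_nb", seed=0))
        clf.fit(X, y)
        # class 0: counts a=3, b=1 -> theta = (4/6, 2/6); class 1: a=0,b=3 -> (1/5, 4/5)
        # doc [1, 1]: p(c) * theta_a * theta_b, prior 1/2 each
        p0 = (4 / 6) * (2 / 6)
        p1 = (1 / 5) * (4 / 5)
        want = np.array([p0, p1]) / (p0 + p1)
        got = clf.predict_proba(sp.csr_matrix(np.array([[1, 1]])))[0]
        assert np.allclose(got, want, atol=1e-12)


class TestPooledMetrics:
    def test_constant_prediction_balanced_classes_kappa_zero(self):
        y = np.repeat([0, 1], 25)
        pred = np.zeros(50, dtype=int)
        rep = _pooled_report(y, pred, np.array([0, 1]),
                             ClassifierSpec("sgd_svm", seed=0), folds=10)
        assert rep.kappa == pytest.approx(0.0, abs=1e-12)

    def test_kappa_never_exceeds_accuracy(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            y = rng.integers(0, 3, 60)
            pred = rng.integers(0, 3, 60)
            rep = _pooled_report(y, pred, np.arange(3),
                                 ClassifierSpec("sgd_svm", seed=0), folds=10)
            acc = (y == pred).mean()
            assert rep.kappa <= acc + 1e-12

    def test_weighted_f1_invariant_under_relabeling(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 4, 80)
        pred = rng.integers(0, 4, 80)
        perm = np.array([2, 3, 1, 0])
        r1 = _pooled_report(y, pred, np.arange(4),
                            ClassifierSpec("sgd_svm", seed=0), folds=10)
        r2 = _pooled_report(perm[y], perm[pred], np.arange(4),
                            ClassifierSpec("sgd_svm", seed=0), folds=10)
        assert r1.f1_weighted == pytest.approx(r2.f1_weighted, abs=1e-12)


class TestSupportVsF1:
    def _report(self, per_class):
        rows = sorted(per_class, key=lambda r: -r[1])
        K = len(rows)
        conf = np.zeros((K, K), dtype=int)
        for i, (_, _, s) in enumerate(rows):
            conf[i, i] = s
        rep = _pooled_report.__wrapped__ if hasattr(_pooled_report, "__wrapped__") else None
        from nephrotext.classify import EvalReport

        return EvalReport(classifier="x", f1_macro=0, f1_weighted=0, kappa=0,
                          per_class=rows, confusion=conf, folds=10, seed=0)

    def test_monotone_f1_gives_rho_one(self):
        rep = self._report([(c, 0.1 * c, 10 * (c + 1)) for c in range(5)])
        assert support_vs_f1(rep)["rho"] == pytest.approx(1.0)

    def test_few_classes_rejected(self):
        rep = self._report([(0, 0.2, 5), (1, 0.4, 9), (2, 0.9, 30)])
        with pytest.raises(ValueError):
            support_vs_f1(rep)

    def test_constant_f1_flagged_undefined(self):
        rep = self._report([(c, 0.5, 10 + c) for c in range(5)])
        assert support_vs_f1(rep)["defined"] is False


class TestCompareClassifiers:
    def test_identical_specs_identical_rows(self, separable_two_class):
        docs, cs = separable_two_class
        spec = ClassifierSpec("sgd_svm", seed=3)
        r1, r2 = compare_classifiers(docs, cs, [spec, spec])
        assert r1.f1_weighted == r2.f1_weighted
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_ranked_by_weighted_f1_and_row_count(self, separable_two_class):
        docs, cs = separable_two_class
        specs = [ClassifierSpec(n, seed=1)
                 for n in ("sgd_svm", "logreg", "multinomial_nb")]
        reports = compare_classifiers(docs, cs, specs)
        assert len(reports) == 3
        f1s = [r.f1_weighted for r in reports]
        assert f1s == sorted(f1s, reverse=True)

    def test_empty_spec_list_rejected(self, separable_two_class):
        docs, cs = separable_two_class
        with pytest.raises(ValueError):
            compare_classifiers(docs, cs, [])
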