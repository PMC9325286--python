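"""Predicting the diagnostic group from the microscopic description.

This is the supervised half of the study: the cluster labels obtained from
the diagnosis sections become weak training labels, and classifiers try to
recover them from the corresponding microscopic description texts.
Bag-of-words specs (SGD-trained linear SVM, MLP, logistic regression,
multinomial naive Bayes) consume tf-idf vectors of the preprocessed
description tokens; the neural specs (CNN, BiLSTM) consume padded token-id
sequences with jointly trained word embeddings.

Evaluation is stratified 10-fold cross-validation; out-of-fold predictions
are pooled and all metrics (macro / weighted F1, Cohen's kappa, per-class
F1 with support, confusion matrix) are computed once on the pooled set, so
the confusion matrix and kappa are well-defined single objects.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.stats import spearmanr
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.linear_model import LogisticRegression, SGDClassifier
from sklearn.metrics import cohen_kappa_score, confusion_matrix, f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import MultinomialNB
from sklearn.neural_network import MLPClassifier

from .cluster_engine import ClusterSet
from .neural import BiLSTMTextClassifier, CNNTextClassifier
from .preprocess import TokenDoc

__all__ = [
    "CLASSIFIER_NAMES",
    "ClassifierSpec",
    "EvalReport",
    "build_sklearn",
    "build_neural",
    "train_predict_cv",
    "support_vs_f1",
    "compare_classifiers",
    "save_eval_report",
]

BOW_NAMES = ("sgd_svm", "mlp", "logreg", "multinomial_nb")
NEURAL_NAMES = ("rnn_embed", "cnn_embed")
CLASSIFIER_NAMES = BOW_NAMES + NEURAL_NAMES


@dataclass(frozen=True)
class ClassifierSpec:
    name: str
    seed: int
    hyperparams: tuple[tuple[str, object], ...] = ()

    def __post_init__(self) -> None:
        if self.name not in CLASSIFIER_NAMES:
            raise ValueError(
                f"unknown classifier {self.name!r}; choose from {CLASSIFIER_NAMES}"
            )

    @property
    def hp(self) -> dict:
        return dict(self.hyperparams)


@dataclass
class EvalReport:
    classifier: str
    f1_macro: float
    f1_weighted: float
    kappa: float
    per_class: list[tuple[int, float, int]]  # (cluster, f1, support), desc f1
    confusion: np.ndarray
    folds: int
    seed: int

    def __post_init__(self) -> None:
        supports = {c: s for c, _, s in self.per_class}
        row_sums = self.confusion.sum(axis=1)
        if int(row_sums.sum()) != int(sum(supports.values())):
            raise ValueError("confusion total disagrees with supports")
        f1s = [f for _, f, _ in self.per_class]
        if any(a < b for a, b in zip(f1s, f1s[1:])):
            raise ValueError("per_class must be sorted by descending f1")


def build_sklearn(spec: ClassifierSpec):
    """Instantiate a bag-of-words classifier from its spec."""
    hp = spec.hp
    if spec.name == "sgd_svm":
        return SGDClassifier(loss="hinge", random_state=spec.seed,
                             max_iter=hp.get("max_iter", 1000))
    if spec.name == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=hp.get("hidden_layer_sizes", (64,)),
            solver="adam", random_state=spec.seed,
            max_iter=hp.get("max_iter", 200),
        )
    if spec.name == "logreg":
        return LogisticRegression(max_iter=hp.get("max_iter", 1000),
                                  random_state=spec.seed)
    if spec.name == "multinomial_nb":
        return MultinomialNB(alpha=hp.get("alpha", 1.0))
    raise ValueError(f"{spec.name} is not a bag-of-words classifier")


def build_neural(spec: ClassifierSpec, n_classes: int):
    """Instantiate a neural classifier (CNN or BiLSTM) from its spec."""
    hp = spec.hp
    common = dict(
        n_classes=n_classes,
        embed_dim=hp.get("embed_dim", 32),
        seed=spec.seed,
        epochs=hp.get("epochs", 30),
        batch_size=hp.get("batch_size", 32),
        lr=hp.get("lr", 1e-2),
    )
    if spec.name == "cnn_embed":
        return CNNTextClassifier(
            n_kernels=hp.get("n_kernels", 32),
            kernel_width=hp.get("kernel_width", 3),
            hidden=hp.get("hidden", 32),
            **common,
        )
    if spec.name == "rnn_embed":
        return BiLSTMTextClassifier(hidden=hp.get("hidden", 32), **common)
    raise ValueError(f"{spec.name} is not a neural classifier")


def _pooled_report(y: np.ndarray, pred: np.ndarray, classes: np.ndarray,
                   spec: ClassifierSpec, folds: int) -> EvalReport:
    per_class_f1 = f1_score(y, pred, labels=classes, average=None, zero_division=0)
    supports = np.array([(y == c).sum() for c in classes])
    rows = [(int(c), float(f), int(s))
            for c, f, s in zip(classes, per_class_f1, supports)]
    rows.sort(key=lambda r: (-r[1], r[0]))
    return EvalReport(
        classifier=spec.name,
        f1_macro=float(f1_score(y, pred, average="macro", zero_division=0)),
        f1_weighted=float(f1_score(y, pred, average="weighted", zero_division=0)),
        kappa=float(cohen_kappa_score(y, pred)),
        per_class=rows,
        confusion=confusion_matrix(y, pred, labels=classes),
        folds=folds,
        seed=spec.seed,
    )


def train_predict_cv(
    descriptions: Sequence[TokenDoc],
    labels: ClusterSet,
    spec: ClassifierSpec,
    n_folds: int = 10,
) -> EvalReport:
    """Stratified cross-validated evaluation of one classifier spec.

    Outlier-labelled documents are excluded.  Out-of-fold predictions are
    pooled before any metric is computed.
    """
    kept = np.flatnonzero(labels.kept_mask)
    y = labels.labels[kept]
    docs = [descriptions[i] for i in kept]
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("classification needs at least 2 classes")
    counts = {int(c): int((y == c).sum()) for c in classes}
    tiny = [c for c, n in counts.items() if n < 2]
    if tiny:
        raise ValueError(f"classes with fewer than 2 documents: {tiny}")
    min_class = min(counts.values())
    folds = n_folds
    if min_class < folds:
        folds = max(2, min_class)
        warnings.warn(
            f"smallest class has {min_class} docs; reducing folds to {folds}"
        )
    pred = np.empty_like(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
    texts = [" ".join(d.tokens) for d in docs]
    for train, test in skf.split(texts, y):
        if spec.name in BOW_NAMES:
            vec = TfidfVectorizer(lowercase=False, token_pattern=r"\S+")
            Xtr = vec.fit_transform([texts[i] for i in train])
            Xte = vec.transform([texts[i] for i in test])
            clf = build_sklearn(spec)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # MLP convergence chatter
                clf.fit(Xtr, y[train])
            pred[test] = clf.predict(Xte)
        else:
            model = build_neural(spec, n_classes=int(classes.max()) + 1)
            model.fit([docs[i] for i in train], y[train])
            pred[test] = model.predict([docs[i] for i in test])
    return _pooled_report(y, pred, classes, spec, folds)


def support_vs_f1(report: EvalReport) -> dict[str, float | bool]:
    """Spearman rank correlation between per-class support and F1.

    A positive correlation reproduces the study's qualitative finding that
    sparsely supported diagnostic groups are harder to recognise.
    """
    if len(report.per_class) < 4:
        raise ValueError("need at least 4 classes for a rank correlation")
    f1s = np.array([f for _, f, _ in report.per_class])
    sup = np.array([s for _, _, s in report.per_class])
    if np.allclose(f1s, f1s[0]):
        return {"rho": float("nan"), "defined": False}
    rho, _ = spearmanr(sup, f1s)
    return {"rho": float(rho), "defined": True}


def compare_classifiers(
    descriptions: Sequence[TokenDoc],
    labels: ClusterSet,
    specs: Sequence[ClassifierSpec],
    n_folds: int = 10,
) -> list[EvalReport]:
    """Evaluate several specs; returns reports ranked by weighted F1."""
    if not specs:
        raise ValueError("need at least one classifier spec")
    reports = [train_predict_cv(descriptions, labels, s, n_folds=n_folds)
               for s in specs]
    reports.sort(key=lambda r: -r.f1_weighted)
    return reports


def save_eval_report(report: EvalReport, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rec = {
        "classifier": report.classifier,
        "f1_macro": report.f1_macro,
        "f1_weighted": report.f1_weighted,
        "kappa": report.kappa,
        "per_class": report.per_class,
        "confusion": report.confusion.tolist(),
        "folds": report.folds,
        "seed": report.seed,
    }
    path.write_text(json.dumps(rec, sort_keys=True, indent=1) + "\n", encoding="utf-8")
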