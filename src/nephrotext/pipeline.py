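"""End-to-end orchestration of the two-stage report study.

``run_study`` wires the stages together from one config and one global
seed: corpus (synthetic or from disk) -> section segmentation ->
preprocessing -> clustering with every configured backend -> scorecard
evaluation -> selection of the best cluster-set -> keyword extraction ->
description-based classification.  Every stage seed is derived from the
global seed and the stage name, so a rerun with the same config and seed
reproduces the study byte for byte.

The selection rule ranks cluster-sets by cls accuracy (tie-break: lower
relative entropy), after discarding cluster-sets that rejected too many
documents as outliers (kept fraction below a configurable threshold) —
heavy outlier loss shrinks the corpus the classification stage can use.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import cluster_engine as ce
from .classify import ClassifierSpec, EvalReport, compare_classifiers, save_eval_report
from .cluster_eval import (AuthorConfoundReport, ClusterSetMetrics,
                           author_confound, evaluate_clusterset, project_2d)
from .corpus_io import Corpus, segment_corpus, write_corpus
from .keyword_extract import KeywordTable, keywords_svm, keywords_tfidf, save_keyword_table
from .preprocess import PreprocessConfig, preprocess_text, vectorize
from .synth_corpus import SynthSpec, generate, write_truth

__all__ = ["RunConfig", "StudyResult", "derive_seed", "run_study",
           "scorecard_table", "serialize_study"]

DEFAULT_BACKENDS = ("kmeans", "lda", "gsdpmm", "hdbscan", "doc2vec-hdbscan")
DEFAULT_CLASSIFIERS = ("sgd_svm", "mlp", "logreg", "multinomial_nb")


def derive_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed: crc32 of "<seed>:<stage>", kept below 2^31."""
    return zlib.crc32(f"{global_seed}:{stage}".encode()) & 0x7FFFFFFF


@dataclass
class RunConfig:
    seed: int = 0
    synth: Optional[SynthSpec] = None          # generated corpus when set
    corpus_path: Optional[str] = None          # else: sectioned corpus on disk
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    backends: tuple[str, ...] = DEFAULT_BACKENDS
    backend_params: dict = field(default_factory=dict)
    classifiers: tuple[str, ...] = DEFAULT_CLASSIFIERS
    k_range: tuple[int, ...] = tuple(range(6, 21))
    min_cluster_size: int = 10
    kept_fraction_min: float = 0.65
    selection_override: Optional[str] = None   # force a backend manually
    export_projections: bool = True
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        unknown = set(self.backends) - set(DEFAULT_BACKENDS)
        if unknown:
            raise ValueError(f"unknown clustering backends: {sorted(unknown)}")
        if self.synth is None and self.corpus_path is None:
            self.synth = SynthSpec(seed=derive_seed(self.seed, "synth"))


@dataclass
class StudyResult:
    corpus: Corpus
    scorecard: list[ClusterSetMetrics]
    cluster_sets: dict[str, ce.ClusterSet]
    selected: str
    keywords: dict[str, KeywordTable]
    classifier_reports: list[EvalReport]
    confound: Optional[AuthorConfoundReport]
    warnings: list[str] = field(default_factory=list)
    seed: int = 0


def _author_code(report) -> Optional[str]:
    if report.authors is None or not report.authors:
        return None
    return "+".join(sorted(report.authors))


def _drop_tiny_classes(cs: ce.ClusterSet, min_size: int = 2) -> tuple[ce.ClusterSet, list[str]]:
    """Relabel classes below min_size as outliers so CV stays well-posed."""
    labels = cs.labels.copy()
    notes = []
    for c in np.unique(labels[labels >= 0]):
        n = int((labels == c).sum())
        if n < min_size:
            labels[labels == c] = ce.OUTLIER
            notes.append(f"{cs.method}: cluster {c} ({n} docs) set aside for classification")
    out = np.full(labels.shape, ce.OUTLIER, dtype=np.int64)
    for new, old in enumerate(np.unique(labels[labels >= 0])):
        out[labels == old] = new
    return ce.ClusterSet(labels=out, method=cs.method, params=cs.params,
                         seed=cs.seed, doc_ids=cs.doc_ids), notes


def run_study(config: RunConfig) -> StudyResult:
    """Run the full two-stage study; deterministic for a fixed config+seed."""
    out_dir = Path(config.out_dir) if config.out_dir else None
    warnings_log: list[str] = []

    # --- corpus ----------------------------------------------------------
    if config.corpus_path is not None:
        from .corpus_io import load_corpus

        corpus = load_corpus(config.corpus_path)
        truth = None
    else:
        raws, truth = generate(config.synth)
        corpus = segment_corpus(raws)
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_corpus(corpus, out_dir / "corpus.jsonl")
        if truth is not None:
            write_truth(truth, out_dir / "truth.tsv")

    # --- preprocessing ---------------------------------------------------
    diag_docs = [preprocess_text(r.id, r.diagnosis, config.preprocess)
                 for r in corpus.reports]
    desc_docs = [preprocess_text(r.id, r.microscopy, config.preprocess)
                 for r in corpus.reports]
    counts = vectorize(diag_docs, mode="count")
    tfidf = vectorize(diag_docs, mode="tfidf")

    # --- clustering ------------------------------------------------------
    cluster_sets: dict[str, ce.ClusterSet] = {}
    representations: dict[str, tuple[object, str]] = {}
    elbow_k: Optional[int] = None
    bp = config.backend_params

    def _elbow() -> int:
        nonlocal elbow_k
        if elbow_k is None:
            elbow_k = ce.select_k_elbow(tfidf, config.k_range,
                                        seed=derive_seed(config.seed, "elbow"))
        return elbow_k

    for backend in config.backends:
        seed = derive_seed(config.seed, f"cluster:{backend}")
        if backend == "kmeans":
            k = bp.get("kmeans_k") or _elbow()
            cs = ce.cluster_kmeans(tfidf, k=k, seed=seed)
            representations[backend] = (tfidf, "tfidf")
        elif backend == "lda":
            k = bp.get("lda_k") or _elbow()
            cs = ce.cluster_lda(counts, k=k, seed=seed)
            representations[backend] = (tfidf, "tfidf")
        elif backend == "gsdpmm":
            cs = ce.cluster_gsdpmm(
                counts, alpha=bp.get("gsdpmm_alpha", 1.0),
                beta=bp.get("gsdpmm_beta", 0.05),
                k_max=bp.get("gsdpmm_k_max", 40), seed=seed)
            representations[backend] = (tfidf, "tfidf")
        elif backend == "hdbscan":
            red = ce.reduce_umap(tfidf, d=5, seed=seed)
            cs = ce.cluster_hdbscan(red, min_cluster_size=config.min_cluster_size,
                                    doc_ids=list(tfidf.doc_ids), method="hdbscan")
            representations[backend] = (red, "umap5")
        elif backend == "doc2vec-hdbscan":
            emb = ce.embed_corpus_doc2vec(
                diag_docs, dim=bp.get("doc2vec_dim", 64),
                epochs=bp.get("doc2vec_epochs", 30),
                seed=derive_seed(config.seed, "doc2vec"))
            red = ce.reduce_umap(emb, d=5, seed=seed)
            cs = ce.cluster_hdbscan(red, min_cluster_size=config.min_cluster_size,
                                    doc_ids=emb.doc_ids, method="doc2vec-hdbscan")
            representations[backend] = (red, "umap5")
        cluster_sets[backend] = cs
        warnings_log.extend(ce.check_cluster_bounds(cs))

    # --- evaluation ------------------------------------------------------
    scorecard: list[ClusterSetMetrics] = []
    for backend, cs in cluster_sets.items():
        rep, rep_name = representations[backend]
        if cs.n_clusters < 2:
            warnings_log.append(f"{backend}: fewer than 2 clusters, not scored")
            continue
        scorecard.append(
            evaluate_clusterset(diag_docs, counts, rep, cs,
                                seed=derive_seed(config.seed, f"eval:{backend}"),
                                representation_name=rep_name)
        )

    if not scorecard:
        raise RuntimeError("no backend produced a scoreable cluster-set")

    # --- selection -------------------------------------------------------
    n_docs = len(corpus.reports)
    if config.selection_override is not None:
        selected = config.selection_override
        if selected not in cluster_sets:
            raise ValueError(f"selection override {selected!r} not among backends")
    else:
        eligible = [m for m in scorecard
                    if m.corpus_size / n_docs >= config.kept_fraction_min]
        pool = eligible or scorecard
        if not eligible:
            warnings_log.append("no cluster-set met the kept-fraction threshold; "
                                "selecting among all")
        best = sorted(pool, key=lambda m: (-m.cls_accuracy, m.rel_entropy))[0]
        selected = best.method

    # --- keywords --------------------------------------------------------
    sel_cs = cluster_sets[selected]
    keywords = {
        "tfidf": keywords_tfidf(counts, sel_cs),
        "svm": keywords_svm(tfidf, sel_cs,
                            seed=derive_seed(config.seed, "keywords")),
    }

    # --- classification --------------------------------------------------
    cls_labels, notes = _drop_tiny_classes(sel_cs)
    warnings_log.extend(notes)
    specs = [ClassifierSpec(name=n, seed=derive_seed(config.seed, f"clf:{n}"))
             for n in config.classifiers]
    reports = compare_classifiers(desc_docs, cls_labels, specs)

    # --- author confound -------------------------------------------------
    author_codes = [_author_code(r) for r in corpus.reports]
    confound = None
    if any(a is not None for a in author_codes):
        confound = author_confound(sel_cs, author_codes)

    result = StudyResult(
        corpus=corpus, scorecard=scorecard, cluster_sets=cluster_sets,
        selected=selected, keywords=keywords, classifier_reports=reports,
        confound=confound, warnings=warnings_log, seed=config.seed,
    )

    # --- persistence -----------------------------------------------------
    if out_dir:
        scorecard_table(result.scorecard).to_csv(out_dir / "scorecard.tsv",
                                                 sep="\t", index=False)
        for backend, cs in cluster_sets.items():
            ce.save_clusterset(cs, out_dir / f"clusterset_{backend}.json")
        for method, kt in keywords.items():
            save_keyword_table(kt, out_dir / f"keywords_{method}.tsv")
        for rep in reports:
            save_eval_report(rep, out_dir / f"classifier_{rep.classifier}.json")
        if config.export_projections:
            _export_projection(out_dir / "projection_tfidf.tsv", tfidf, sel_cs,
                               author_codes, derive_seed(config.seed, "proj"))
        (out_dir / "study.json").write_text(serialize_study(result),
                                            encoding="utf-8")
    return result


def _export_projection(path: Path, X, cs: ce.ClusterSet,
                       authors: list[Optional[str]], seed: int) -> None:
    coords = project_2d(X, method="umap", seed=seed)
    df = pd.DataFrame({
        "doc_id": cs.doc_ids if cs.doc_ids else range(coords.shape[0]),
        "x": coords[:, 0], "y": coords[:, 1],
        "cluster": cs.labels,
        "author": [a or "" for a in authors],
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def scorecard_table(scorecard: Sequence[ClusterSetMetrics]) -> pd.DataFrame:
    """Scorecard rows sorted by descending silhouette."""
    if not scorecard:
        raise ValueError("empty scorecard")
    df = pd.DataFrame(
        [{"method": m.method, "s_score": round(m.s_score, 3),
          "cls_accuracy": round(m.cls_accuracy, 3),
          "rel_entropy": round(m.rel_entropy, 3),
          "clusters": m.n_clusters, "corpus_size": m.corpus_size,
          "representation": m.representation}
         for m in scorecard]
    )
    return df.sort_values("s_score", ascending=False).reset_index(drop=True)


def serialize_study(result: StudyResult) -> str:
    """Canonical JSON rendering of a study (used for determinism checks)."""
    payload = {
        "seed": result.seed,
        "selected": result.selected,
        "scorecard": [
            {"method": m.method, "s_score": round(m.s_score, 9),
             "cls_accuracy": round(m.cls_accuracy, 9),
             "rel_entropy": round(m.rel_entropy, 9),
             "clusters": m.n_clusters, "corpus_size": m.corpus_size}
            for m in result.scorecard
        ],
        "labels": {name: cs.labels.tolist()
                   for name, cs in result.cluster_sets.items()},
        "keywords": {method: {str(c): kt.terms(c) for c in sorted(kt.per_cluster)}
                     for method, kt in result.keywords.items()},
        "classifiers": [
            {"name": r.classifier, "f1_weighted": round(r.f1_weighted, 9),
             "f1_macro": round(r.f1_macro, 9), "kappa": round(r.kappa, 9),
             "per_class": r.per_class, "confusion": r.confusion.tolist()}
            for r in result.classifier_reports
        ],
        "author_association": (round(result.confound.association, 9)
                               if result.confound else None),
        "excluded": result.corpus.excluded,
    }
    return json.dumps(payload, sort_keys=True, indent=1) + "\n"
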