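#!/usr/bin/env python
"""Cluster the diagnosis sections with every backend.

Preprocesses the diagnosis texts (stop words with negations retained,
number removal, tf-idf), selects k by the elbow rule, runs k-means, LDA,
GSDPMM, tf-idf->UMAP->HDBSCAN and doc2vec->UMAP->HDBSCAN, and saves each
cluster-set.

    python analysis/03_cluster_diagnoses.py --seed 1 --out results
"""

import argparse
from pathlib import Path

from nephrotext import cluster_engine as ce
from nephrotext.corpus_io import load_corpus
from nephrotext.pipeline import derive_seed
from nephrotext.preprocess import PreprocessConfig, preprocess_text, save_dtm, vectorize


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()
    out = Path(args.out)

    corpus = load_corpus(out / "corpus.jsonl")
    cfg = PreprocessConfig()
    diag = [preprocess_text(r.id, r.diagnosis, cfg) for r in corpus.reports]
    counts = vectorize(diag, "count")
    tfidf = vectorize(diag, "tfidf")
    save_dtm(counts, out / "diagnosis_counts")
    print(f"vocabulary: {len(counts.vocabulary)} terms over {len(diag)} documents")

    k = ce.select_k_elbow(tfidf, range(6, 21), seed=derive_seed(args.seed, "elbow"))
    print(f"elbow-selected k = {k}")

    sets = {
        "kmeans": ce.cluster_kmeans(tfidf, k=k,
                                    seed=derive_seed(args.seed, "cluster:kmeans")),
        "lda": ce.cluster_lda(counts, k=k,
                              seed=derive_seed(args.seed, "cluster:lda")),
        "gsdpmm": ce.cluster_gsdpmm(counts,
                                    seed=derive_seed(args.seed, "cluster:gsdpmm")),
    }
    red = ce.reduce_umap(tfidf, d=5, seed=derive_seed(args.seed, "cluster:hdbscan"))
    sets["hdbscan"] = ce.cluster_hdbscan(red, min_cluster_size=10,
                                         doc_ids=list(tfidf.doc_ids))
    emb = ce.embed_corpus_doc2vec(diag, seed=derive_seed(args.seed, "doc2vec"))
    red2 = ce.reduce_umap(emb, d=5,
                          seed=derive_seed(args.seed, "cluster:doc2vec-hdbscan"))
    sets["doc2vec-hdbscan"] = ce.cluster_hdbscan(red2, min_cluster_size=10,
                                                 doc_ids=emb.doc_ids,
                                                 method="doc2vec-hdbscan")

    for name, cs in sets.items():
        ce.save_clusterset(cs, out / f"clusterset_{name}.json")
        note = "; ".join(ce.check_cluster_bounds(cs)) or "within 10..20 band"
        print(f"{name:16s} K={cs.n_clusters:3d} kept={cs.corpus_size_kept:4d}  ({note})")


if __name__ == "__main__":
    main()
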