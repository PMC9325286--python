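#!/usr/bin/env python
"""Score every cluster-set and select the best one.

Computes the three cluster metrics (silhouette in the representation the
clusterer consumed, SVM-based cls accuracy, relative document entropy),
prints the scorecard, applies the selection rule (max cls accuracy, tie ->
lower entropy, kept fraction >= 0.65), quantifies the author confound and
exports a 2-D projection.

    python analysis/04_evaluate_and_select.py --seed 1 --out results
"""

import argparse
from pathlib import Path

import pandas as pd

from nephrotext import cluster_engine as ce
from nephrotext.cluster_eval import author_confound, evaluate_clusterset, project_2d
from nephrotext.corpus_io import load_corpus
from nephrotext.pipeline import derive_seed, scorecard_table
from nephrotext.preprocess import PreprocessConfig, preprocess_text, vectorize

BACKENDS = ("kmeans", "lda", "gsdpmm", "hdbscan", "doc2vec-hdbscan")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results")
    ap.add_argument("--kept-fraction-min", type=float, default=0.65)
    args = ap.parse_args()
    out = Path(args.out)

    corpus = load_corpus(out / "corpus.jsonl")
    cfg = PreprocessConfig()
    diag = [preprocess_text(r.id, r.diagnosis, cfg) for r in corpus.reports]
    counts = vectorize(diag, "count")
    tfidf = vectorize(diag, "tfidf")

    rows = []
    for name in BACKENDS:
        cs = ce.load_clusterset(out / f"clusterset_{name}.json")
        if name.endswith("hdbscan"):
            if name == "hdbscan":
                rep = ce.reduce_umap(tfidf, d=5,
                                     seed=derive_seed(args.seed, "cluster:hdbscan"))
            else:
                emb = ce.embed_corpus_doc2vec(
                    diag, seed=derive_seed(args.seed, "doc2vec"))
                rep = ce.reduce_umap(
                    emb, d=5, seed=derive_seed(args.seed, "cluster:doc2vec-hdbscan"))
            rep_name = "umap5"
        else:
            rep, rep_name = tfidf, "tfidf"
        rows.append(evaluate_clusterset(diag, counts, rep, cs,
                                        seed=derive_seed(args.seed, f"eval:{name}"),
                                        representation_name=rep_name))

    table = scorecard_table(rows)
    table.to_csv(out / "scorecard.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    n_docs = len(corpus.reports)
    eligible = [m for m in rows if m.corpus_size / n_docs >= args.kept_fraction_min]
    best = sorted(eligible or rows, key=lambda m: (-m.cls_accuracy, m.rel_entropy))[0]
    (out / "selected_backend.txt").write_text(best.method + "\n")
    print(f"\nselected backend: {best.method} "
          f"(cls accuracy {best.cls_accuracy:.3f}, "
          f"rel entropy {best.rel_entropy:.3f})")

    sel = ce.load_clusterset(out / f"clusterset_{best.method}.json")
    authors = ["+".join(sorted(r.authors)) if r.authors else None
               for r in corpus.reports]
    conf = author_confound(sel, authors)
    print(f"author confound (Cramér's V): {conf.association:.3f}")

    coords = project_2d(tfidf, method="umap", seed=derive_seed(args.seed, "proj"))
    pd.DataFrame({"doc_id": [r.id for r in corpus.reports],
                  "x": coords[:, 0], "y": coords[:, 1],
                  "cluster": sel.labels,
                  "author": [a or "" for a in authors]}).to_csv(
        out / "projection_2d.tsv", sep="\t", index=False, float_format="%.6f")


if __name__ == "__main__":
    main()
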