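#!/usr/bin/env python
"""Extract per-cluster keywords from the selected cluster-set.

Both extraction methods (cluster-pooled tf-idf; linear-SVM weight analysis
restricted to correctly predicted documents) write top-10 tables, which is
what domain experts would annotate with diagnostic group names.

    python analysis/05_extract_keywords.py --seed 1 --out results
"""

import argparse
from pathlib import Path

from nephrotext import cluster_engine as ce
from nephrotext.corpus_io import load_corpus
from nephrotext.keyword_extract import keywords_svm, keywords_tfidf, save_keyword_table
from nephrotext.pipeline import derive_seed
from nephrotext.preprocess import PreprocessConfig, preprocess_text, vectorize


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()
    out = Path(args.out)

    corpus = load_corpus(out / "corpus.jsonl")
    selected = (out / "selected_backend.txt").read_text().strip()
    cs = ce.load_clusterset(out / f"clusterset_{selected}.json")
    cfg = PreprocessConfig()
    diag = [preprocess_text(r.id, r.diagnosis, cfg) for r in corpus.reports]
    counts = vectorize(diag, "count")
    tfidf = vectorize(diag, "tfidf")

    kt = keywords_tfidf(counts, cs, top_n=10)
    ks = keywords_svm(tfidf, cs, top_n=10, seed=derive_seed(args.seed, "keywords"))
    save_keyword_table(kt, out / "keywords_tfidf.tsv")
    save_keyword_table(ks, out / "keywords_svm.tsv")

    print(f"keywords for the {selected} cluster-set "
          f"({cs.n_clusters} clusters); top-5 shown per method:")
    for c in sorted(kt.per_cluster):
        print(f"  cluster {c:2d}  tfidf: {', '.join(kt.terms(c)[:5])}")
        print(f"             svm:   {', '.join(ks.terms(c)[:5])}")


if __name__ == "__main__":
    main()
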