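#!/usr/bin/env python
"""Predict the diagnostic group from the microscopic description.

The selected cluster-set provides the weak labels; bag-of-words classifiers
(SGD-SVM, MLP, logistic regression, multinomial NB) are compared under
stratified ten-fold cross-validation.  Writes the comparison table, the
per-class F1/support table of the best model, and reports the
support-difficulty rank correlation.

    python analysis/06_classify_descriptions.py --seed 1 --out results
"""

import argparse
from pathlib import Path

import pandas as pd

from nephrotext import cluster_engine as ce
from nephrotext.classify import (ClassifierSpec, compare_classifiers,
                                 save_eval_report, support_vs_f1)
from nephrotext.corpus_io import load_corpus
from nephrotext.pipeline import _drop_tiny_classes, derive_seed
from nephrotext.preprocess import PreprocessConfig, preprocess_text

CLASSIFIERS = ("sgd_svm", "mlp", "logreg", "multinomial_nb")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()
    out = Path(args.out)

    corpus = load_corpus(out / "corpus.jsonl")
    selected = (out / "selected_backend.txt").read_text().strip()
    cs = ce.load_clusterset(out / f"clusterset_{selected}.json")
    cs, notes = _drop_tiny_classes(cs)
    for n in notes:
        print(n)
    cfg = PreprocessConfig()
    desc = [preprocess_text(r.id, r.microscopy, cfg) for r in corpus.reports]

    specs = [ClassifierSpec(name=n, seed=derive_seed(args.seed, f"clf:{n}"))
             for n in CLASSIFIERS]
    reports = compare_classifiers(desc, cs, specs)

    table = pd.DataFrame([{"classifier": r.classifier,
                           "f1_weighted": round(r.f1_weighted, 3),
                           "f1_macro": round(r.f1_macro, 3),
                           "kappa": round(r.kappa, 3)} for r in reports])
    table.to_csv(out / "classifier_comparison.tsv", sep="\t", index=False)
    print(table.to_string(index=False))

    best = reports[0]
    save_eval_report(best, out / f"classifier_{best.classifier}.json")
    per_class = pd.DataFrame(best.per_class, columns=["cluster", "f1", "support"])
    per_class.to_csv(out / "per_class_f1.tsv", sep="\t", index=False,
                     float_format="%.3f")
    print(f"\nper-class F1 of {best.classifier} (descending):")
    print(per_class.to_string(index=False))

    rho = support_vs_f1(best)
    if rho["defined"]:
        print(f"\nSpearman rho(support, F1) = {rho['rho']:.3f} "
              "(positive: small groups are harder)")


if __name__ == "__main__":
    main()
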