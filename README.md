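# nephrotext

Weakly supervised diagnostic-group discovery and prediction for sectioned
(nephro)pathology reports.

## The problem

Nephropathology produces excellent free-text data: every kidney biopsy gets a
report whose **microscopic description** section records the histomorphology
and whose **diagnosis** section (German: *Beurteilung*) states the conclusion.
Manually labelled corpora, however, are scarce. This package implements a
two-stage analysis that turns the reports themselves into a labelled
classification problem:

1. **Clustering (weak labelling).** The diagnosis sections are clustered
   unsupervised into a bounded number of diagnostic groups (target band
   10–20 clusters) with five backends: k-means and LDA on bag-of-words
   vectors, a collapsed Gibbs sampler for the Dirichlet-process multinomial
   mixture (GSDPMM), and two density-based paths (tf-idf → UMAP → HDBSCAN
   and doc2vec → UMAP → HDBSCAN) that can reject documents as outliers.
   Competing cluster-sets are scored with three complementary metrics and
   per-cluster keywords are extracted so experts can name the groups.
2. **Classification (prediction).** The winning cluster labels become weak
   training labels, and classifiers (SGD-trained linear SVM, MLP, logistic
   regression, multinomial naive Bayes, plus small CNN/BiLSTM networks with
   jointly trained word embeddings) try to predict the diagnostic group from
   the *description* section alone — testing whether the morphology text
   carries enough information to reach the diagnosis.

Because real clinical corpora of this kind are withheld for privacy, the
package ships a synthetic report generator with planted ground truth
(diagnostic groups, author styles, malformed reports, outliers), so every
stage is testable end to end.

It is aimed at clinical-NLP researchers and pathology informatics groups who
want a tested, reproducible reference pipeline for report-based weak
supervision, or a harness for benchmarking their own clustering/classification
components against planted truth.

## The statistics at the core

For a cluster-set with clusters *j = 1..m*, quality is scored without any
gold labels by:

- **s-score** — mean silhouette coefficient over non-outlier documents, in
  the representation the clusterer consumed;
- **relative document entropy** —
  `mean_j ( mean_i KL( p_ij ‖ q_j ) )`,
  where `p_ij` is document *i*'s term-frequency distribution and `q_j` its
  cluster's pooled distribution (both normalised over the cluster
  vocabulary; natural log). Low values mean vocabulary-homogeneous clusters;
- **cls accuracy** — stratified 10-fold cross-validated accuracy of a linear
  SVM predicting the cluster label from the diagnosis tf-idf vector: a
  shape-free measure of how learnable the partition is.

GSDPMM resamples each document's component *z_d* from

`p(z_d = k) ∝ m_k · Π_w [Γ(n_k(w)+c_d(w)+β)/Γ(n_k(w)+β)] / [Γ(n_k+N_d+Vβ)/Γ(n_k+Vβ)]`

(with `m_k → α` for a new component), inferring the number of diagnostic
groups from the data.

Classification is evaluated with pooled out-of-fold predictions: weighted and
macro F1, Cohen's κ, per-class F1 with support, and confusion matrices.

## Worked example

The `analysis/` directory is a numbered narrative over the library. On the
default synthetic corpus (600 reports, 12 groups, power-law sizes):

```bash
python analysis/01_generate_corpus.py  --seed 1 --out results
python analysis/02_segment_corpus.py            --out results
python analysis/03_cluster_diagnoses.py --seed 1 --out results
python analysis/04_evaluate_and_select.py --seed 1 --out results
python analysis/05_extract_keywords.py  --seed 1 --out results
python analysis/06_classify_descriptions.py --seed 1 --out results
```

Script 02 prints

```
kept 566 of 600 reports (34 excluded); mean words/report = 135.2
exclusions match the malformed ground truth exactly (precision = recall = 1.0)
```

— segmentation excludes exactly the reports whose required header tag is
missing. Script 04 prints the scorecard (sorted by s-score):

```
         method  s_score  cls_accuracy  rel_entropy  clusters  corpus_size
        hdbscan    0.914         1.000        1.154         9          558
doc2vec-hdbscan    0.793         0.956        1.147        14          549
         gsdpmm    0.247         1.000        1.092        13          566
         kmeans    0.163         0.977        1.215        11          566
            lda    0.111         0.949        1.238        11          566
selected backend: gsdpmm (cls accuracy 1.000, rel entropy 1.092)
author confound (Cramér's V): 0.316
```

The density-based paths have by far the cleanest geometry (highest
s-scores) but discard documents as outliers. HDBSCAN and GSDPMM tie on cls
accuracy at 1.000, and the selection rule breaks the tie toward the lower
relative entropy, so GSDPMM wins — while labelling every document. The moderate author association (V ≈ 0.32) reflects the
generator's planted author-style confound. Script 05 shows that each
cluster's top keywords are exactly its group's planted marker terms — and
that GSDPMM put the background-only outlier documents into a cluster of
their own (keywords `bg_t0, bg_t1, ...`). Script 06 closes the loop from
the description sections:

```
    classifier  f1_weighted  f1_macro  kappa
        logreg        0.918     0.862  0.887
       sgd_svm        0.911     0.858  0.877
           mlp        0.907     0.845  0.875
multinomial_nb        0.845     0.656  0.818
Spearman rho(support, F1) = 0.746 (positive: small groups are harder)
```

The positive support–F1 correlation reproduces the central qualitative
finding of report-based weak supervision: sparsely supported diagnostic
groups are systematically harder to recognise.

`nephrotext.pipeline.run_study` runs the same study as a single seeded call
and is byte-reproducible for a fixed seed.

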