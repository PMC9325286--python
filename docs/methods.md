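# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of the `nephrotext` pipeline. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Pipeline overview and assumptions

A report is assumed to be a plain-text document whose sections are announced
by German header keywords at line starts ("Klinische Angaben", "Mikroskopie",
"Beurteilung"; synonyms configurable). Matching is case-insensitive, an
optional trailing colon is absorbed, and the *first* occurrence of a role's
tag wins — multiple occurrences of the same header are rare and ambiguous,
and taking the first is the deterministic reading. A report from which a
nonempty microscopy *and* diagnosis section cannot be recovered is excluded;
exclusion is a counted value, never an error, so segmentation statistics
stay auditable.

The analysis assumes the two sections carry complementary signals: the
diagnosis section is short and vocabulary-dense (good for clustering), the
description section is longer and morphology-flavoured (the input of the
prediction task). Both stages model text as bags of words; word order is
only used by the optional neural classifiers.

## Preprocessing

Fixed order: lowercase → punctuation strip → whitespace tokenize → number
removal → stop-word filtering → lemmatization (+ custom replacements) → MWE
merging. The pipeline is idempotent (re-running it on its own output is a
no-op), which the tests check.

- **Stop words.** A general-purpose German list ships with the package;
  negation terms ("kein", "keine", "nicht", "ohne", …) are *removed from the
  list programmatically* because negated findings ("no necrosis") are
  diagnostically opposite to positive ones. "ca" (approx.) is added.
- **Number removal** deletes tokens consisting solely of digits and
  punctuation (dates, "5%", identifiers) but keeps alphanumeric shorthand
  ("m1", "e0", "s1" — Oxford-classification codes are topic words).
- **Lemmatization** is a pluggable term→term callable with identity default,
  keeping the package language-independent; a German tagger can be plugged
  in without code changes.
- **tf-idf** is the smoothed variant idf = ln((1+n)/(1+df)) + 1 with
  per-document L2 normalisation — it avoids zero idf and division by zero
  and is the scikit-learn default, so externally produced matrices are
  comparable.

## Clustering backends

| backend | representation | cluster count | outliers |
|---|---|---|---|
| k-means | tf-idf | elbow-selected k | no |
| LDA (argmax topic) | counts | elbow-selected k | no |
| GSDPMM | counts | inferred (α, β) | no |
| HDBSCAN | UMAP(5) of tf-idf | inferred (min size) | yes |
| doc2vec→HDBSCAN | UMAP(5) of PV-DBOW | inferred (min size) | yes |

- **Elbow rule.** k maximising the vertical distance between the normalised
  inertia curve and its endpoint chord; ties go to the smaller k; a flat
  curve falls back to the smallest k with a warning.
- **LDA restarts.** Single-restart variational EM reliably lands in local
  optima where one topic absorbs two groups (observed even on fully
  separable corpora). `cluster_lda` therefore runs 8 random restarts plus
  one restart warm-started from a k-means partition of the L2-normalised
  count rows, and keeps the solution with the highest evidence lower bound.
  The warm start must also refresh scikit-learn's cached Dirichlet
  expectation (`exp_dirichlet_component_`), otherwise the E-step silently
  uses the random initialisation.
- **GSDPMM.** Collapsed Gibbs sampler for the Dirichlet-process multinomial
  mixture; defaults α = 1.0 (prior openness to new components), β = 0.05
  (topic sparsity; small β favours vocabulary-coherent components),
  30 sweeps, labels from the final sweep, at most 40 simultaneously occupied
  components. The conditional assignment probabilities are computed with
  log-gamma arithmetic and are verified in the tests against an explicit
  slot-product enumeration; occupied-component count is checked to be
  nonincreasing in β.
- **UMAP** defaults: 5 components for clustering, 2 for plotting,
  n_neighbors = 15, min_dist = 0.1, fixed seed, single-threaded — values in
  the range customary for document visualisation; determinism matters more
  here than marginal embedding quality.
- **doc2vec** is an in-package PV-DBOW trainer (negative sampling, 5 noise
  words from the unigram^0.75 distribution, dim 64, 30 epochs, linearly
  decaying learning rate 0.05 → 0.001). It is deliberately minimal: its job
  in this pipeline is to give semantically coherent document vectors to
  UMAP/HDBSCAN, not to be a general embedding library.
- **Cluster-count band.** The study design targets 10–20 clusters; leaving
  the band produces a warning, never an error (legitimate cluster-sets may
  fall outside it).

## Cluster-set metrics

- **Silhouette** is computed in the representation the clusterer consumed
  (tf-idf for the bag-of-words backends, the reduced embedding for the
  HDBSCAN paths) and the space is recorded in the scorecard row — silhouette
  values across different spaces are not directly comparable and the
  scorecard makes that visible.
- **Relative document entropy** uses KL divergence with natural log. For
  document i in cluster j, p is the document's term counts normalised over
  the *cluster vocabulary* (terms with nonzero pooled count) and q the
  pooled cluster distribution normalised likewise. Because the pool includes
  the document itself, q > 0 wherever p > 0 and the divergence is finite
  without smoothing. Cluster means are averaged unweighted across clusters.
  Singleton clusters contribute exactly 0 (a document equals its own pool).
- **cls accuracy** uses stratified 10-fold cross-validation (pooled correct
  count) rather than in-sample accuracy, which would be optimistically
  biased; clusters smaller than the fold count reduce the fold count with a
  warning. The SVM is a linear SVC on tf-idf of the diagnosis sections.
- **Outliers** (label −1) are excluded from all three metrics; the tests
  check that adding outlier documents changes nothing.

## Keywords and naming

The tf-idf extractor pools each cluster into one pseudo-document and
computes tf-idf across pseudo-documents — keyword contrast is a
cluster-level, not document-level, notion here. The SVM extractor fits a
linear one-vs-rest SVM on all kept documents, identifies the correctly
predicted subset, *re-fits* on that subset, and reports the top positive
weights per cluster; restricting to correctly predicted documents removes
boundary cases whose weights blur the cluster signature. Ties are broken
lexicographically everywhere so tables are reproducible. Cluster naming is
a human step: an annotation TSV (cluster, name, strength ∈ {strong, weak})
is joined to the table, and unnamed clusters are legal.

## Classification stage

Bag-of-words classifiers consume tf-idf of the preprocessed description
tokens (vectorizer fit on each training fold only). The neural classifiers
consume padded token-id sequences capped at the 95th-percentile training
length: a CNN (embedding → 1-D convolution with 32 kernels of width 3,
ReLU → global max pooling → dense ReLU → dense softmax) and a BiLSTM
(embedding → one bidirectional LSTM layer, final hidden states of both
directions → softmax head), both implemented in numpy with manual
backpropagation (verified against finite differences in the tests) and
Adam. Embeddings are trained jointly with the classifier.

Metrics are computed on **pooled out-of-fold predictions**, so Cohen's κ
and the confusion matrix are single well-defined objects; per-fold
averaging would leave them ambiguous. Both weighted and macro F1 are
reported; the comparison table ranks by weighted F1. Classes with fewer
than two documents cannot be stratified and are set aside (relabelled as
outliers) before classification, with a logged note.

## Synthetic-data generator

The generator emulates the structure of a sectioned nephropathology
archive. Defaults (the study conditions): K = 12 groups, n = 600 reports,
power-law group sizes (exponent 1.5, floor 8 — long-tailed supports, rare
diseases are rare), vocabulary 2000 terms of which 60% is split into 2·K
group-exclusive slices (diagnosis and description separately) and the rest
is shared background, 3 exclusive marker terms per group per section
carrying 40% of the group-slice mass, section lengths Poisson with means
12/90/45 (clinical/description/diagnosis; ≈136 words per report), 3 authors
with 8 function words each at a 10% token rate and cluster bias 0.3, 5%
numeric noise tokens, 6.6% malformed reports, 3% outliers, overlap 0.3 and
description–diagnosis coupling 0.9.

Per section token: numeric noise (rate 0.05) → author word (rate 0.1) →
background with probability `overlap` → group term otherwise. `overlap`
dials clustering difficulty from separable (0) to indistinguishable (1);
`coupling` is the probability that the description is drawn from the same
group as the diagnosis — at 0 the description carries no label signal and
classifiers must fall to the permutation null. Outlier documents draw from
background only; malformed reports omit one required header. An `audit`
operation chi-squares the marker frequencies against the token model and
checks malformed/outlier counts against binomial 99% intervals.

What the generator does **not** emulate: real German clinical language
(marker terms are synthetic strings like `grp3_diag_m1`, deliberately
alphanumeric so number removal leaves them alone), spelling variation,
section-internal discourse structure, correlated comorbidities, or
label noise in the diagnosis itself. Passing tests therefore demonstrate
algorithmic correctness and the qualitative phenomena (confounds,
imbalance effects), not clinical performance.

### Experiment designs used in the acceptance tests

- *Parameter recovery* uses balanced groups (12 × 50) with author styling
  off — the canonical design for testing whether a backend can recover
  planted structure. With the default power-law imbalance and author words
  on, the dominant group legitimately splits along author style (the very
  confound the pipeline's `author_confound` report is for), which is a
  property of the data, not of the algorithms.
- *Support–difficulty* uses the default power-law imbalance at overlap 0.95
  and coupling 0.85 — the noise level at which the overall weighted F1 sits
  near 0.6 and the smallest groups become unlearnable, i.e. the difficulty
  regime weakly supervised report classification actually operates in.
- Problem sizes throughout (n = 600, 10-seed repetitions, 20-permutation
  nulls) are desk-scale choices that keep the full suite in minutes while
  leaving each effect statistically unambiguous.

## Determinism and seeding

Every stage seed is derived as `crc32("<global_seed>:<stage_name>") mod
2^31`, so stages are independently seeded, no seed is reused, and the whole
study is byte-reproducible (`serialize_study` output is compared verbatim
in the tests). UMAP runs single-threaded with a fixed random state; the
in-package doc2vec, GSDPMM and neural trainers each consume a single numpy
`Generator`.

## Selection rule

Backends are ranked by cls accuracy (tie-break: lower relative entropy)
among cluster-sets that kept at least 65% of documents — heavy outlier
rejection shrinks the corpus available to the classification stage and is
penalised for that reason, not for geometry. The rule is configurable and
can be overridden manually (`selection_override`), since choosing a
cluster-set in practice also involves expert review of the keyword tables,
which no scalar metric captures.

## Known limitations

- Transformer-based embedding or fine-tuning paths are out of scope;
  externally produced document-embedding matrices can be ingested
  (`load_external_embedding`) and clustered with the UMAP→HDBSCAN path.
- The scorecard's silhouettes live in per-backend spaces (recorded per row)
  and should not be compared across representations.
- The neural classifiers are small by design and train on CPU in seconds to
  minutes; they are reference implementations of the two architectures, not
  performance-tuned models.
- `cls_accuracy` and the SVM keyword extractor share the linear-SVM family;
  a cluster-set optimised to be SVM-learnable will look good on both. The
  relative-entropy metric is the counterweight.
- Cramér's V on the cluster × author table is reported without small-sample
  bias correction; under independence its sampling mean at a few hundred
  documents is ≈0.05–0.08, not 0.
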