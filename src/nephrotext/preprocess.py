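"""Bag-of-words preprocessing for German report sections.

The pipeline keeps the vocabulary small and diagnostically meaningful:
lowercasing, punctuation stripping, removal of purely numeric tokens
(dates, quantities, identifiers), negation-preserving stop-word filtering,
pluggable lemmatization with custom term replacements, and merging of
multi-word expressions ("lupus nephritis" -> "lupus_nephritis").  Cleaned
token documents are then vectorized into count or tf-idf document-term
matrices.

Two deliberate asymmetries:

* Negations ("kein", "keine", "nicht", ...) are removed from the stop-word
  base list because "no necrosis" and "necrosis" are different findings.
* Alphanumeric shorthand such as Oxford-classification codes ("m1", "e0",
  "s1") is kept; only tokens made of digits and punctuation are dropped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.io import mmread, mmwrite
from sklearn.feature_extraction.text import CountVectorizer, TfidfTransformer

__all__ = [
    "PreprocessConfig",
    "TokenDoc",
    "DocTermMatrix",
    "default_german_stopwords",
    "tokenize_clean",
    "merge_mwe",
    "lemmatize",
    "preprocess_text",
    "vectorize",
    "save_dtm",
    "load_dtm",
]

#: Negation terms retained by default despite being common function words.
DEFAULT_NEGATION_TERMS = ("kein", "keine", "keinem", "keinen", "keiner",
                          "keines", "nicht", "nichts", "ohne")

_PUNCT_RX = re.compile(r"[^\w\s]", re.UNICODE)
_NUMERIC_TOKEN_RX = re.compile(r"^[\d\W_]+$")  # digits/punct/underscore only


def default_german_stopwords() -> frozenset[str]:
    """Base German stop-word list shipped with the package."""
    text = resources.files("nephrotext.data").joinpath("de_stopwords.txt").read_text(
        encoding="utf-8"
    )
    return frozenset(
        w.strip() for w in text.splitlines() if w.strip() and not w.startswith("#")
    )


@dataclass(frozen=True)
class PreprocessConfig:
    """Configuration of the token-cleaning pipeline.

    ``stopword_removals`` are deleted from the base list (negation retention);
    ``stopword_additions`` extend it (e.g. "ca" for German "approx.").
    """

    stopwords: frozenset[str] = field(default_factory=default_german_stopwords)
    stopword_removals: tuple[str, ...] = DEFAULT_NEGATION_TERMS
    stopword_additions: tuple[str, ...] = ("ca",)
    mwe_list: tuple[tuple[str, ...], ...] = ()
    lemma_replacements: dict[str, str] = field(default_factory=dict)
    remove_numbers: bool = True
    lowercase: bool = True
    strip_punct: bool = True

    def __post_init__(self) -> None:
        for seq in self.mwe_list:
            if len(seq) < 2:
                raise ValueError(f"MWE sequences need length >= 2, got {seq!r}")

    @property
    def effective_stopwords(self) -> frozenset[str]:
        final = (self.stopwords - set(self.stopword_removals)) | set(
            self.stopword_additions
        )
        assert not (final & set(self.stopword_removals))
        return frozenset(final)


@dataclass(frozen=True)
class TokenDoc:
    """One document as an ordered list of cleaned tokens."""

    doc_id: str
    tokens: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(not t for t in self.tokens):
            raise ValueError("tokens must be nonempty strings")


def tokenize_clean(text: str, config: PreprocessConfig = PreprocessConfig()) -> list[str]:
    """Lowercase, strip punctuation, tokenize, drop numbers and stop words."""
    if config.lowercase:
        text = text.lower()
    if config.strip_punct:
        text = _PUNCT_RX.sub(" ", text)
    tokens = text.split()
    if config.remove_numbers:
        tokens = [t for t in tokens if not _NUMERIC_TOKEN_RX.match(t)]
    stop = config.effective_stopwords
    return [t for t in tokens if t not in stop]


def merge_mwe(
    tokens: Sequence[str], mwe_list: Sequence[Sequence[str]]
) -> list[str]:
    """Merge multi-word expressions into single underscore-joined tokens.

    Matching is leftmost-longest: at each position the longest matching
    expression wins and scanning resumes after it.
    """
    if not mwe_list:
        return list(tokens)
    by_first: dict[str, list[tuple[str, ...]]] = {}
    for seq in mwe_list:
        by_first.setdefault(seq[0], []).append(tuple(seq))
    for seqs in by_first.values():
        seqs.sort(key=len, reverse=True)
    out: list[str] = []
    i = 0
    n = len(tokens)
    while i < n:
        merged = False
        for seq in by_first.get(tokens[i], ()):
            L = len(seq)
            if i + L <= n and tuple(tokens[i : i + L]) == seq:
                out.append("_".join(seq))
                i += L
                merged = True
                break
        if not merged:
            out.append(tokens[i])
            i += 1
    return out


def lemmatize(
    tokens: Sequence[str],
    lemmatizer: Optional[Callable[[str], str]] = None,
    replacements: Optional[dict[str, str]] = None,
) -> list[str]:
    """Apply a pluggable term->term lemmatizer, then custom replacements.

    The default lemmatizer is the identity, which keeps the pipeline
    language-independent; a German tagger can be plugged in as a callable.
    Output length always equals input length.
    """
    lemmatizer = lemmatizer or (lambda t: t)
    replacements = replacements or {}
    out = [lemmatizer(t) for t in tokens]
    return [replacements.get(t, t) for t in out]


def preprocess_text(
    doc_id: str,
    text: str,
    config: PreprocessConfig = PreprocessConfig(),
    lemmatizer: Optional[Callable[[str], str]] = None,
) -> TokenDoc:
    """Full pipeline: clean -> lemmatize (+replacements) -> merge MWEs."""
    tokens = tokenize_clean(text, config)
    tokens = lemmatize(tokens, lemmatizer, config.lemma_replacements)
    tokens = merge_mwe(tokens, config.mwe_list)
    return TokenDoc(doc_id=doc_id, tokens=tuple(tokens))


@dataclass
class DocTermMatrix:
    """Sparse document-term matrix over a fixed vocabulary.

    ``mode`` is ``"count"`` (raw term frequencies) or ``"tfidf"``
    (tf x smoothed idf with per-document L2 normalization).
    """

    matrix: sp.csr_matrix
    vocabulary: list[str]
    doc_ids: list[str]
    mode: str

    def __post_init__(self) -> None:
        n, v = self.matrix.shape
        if n != len(self.doc_ids) or v != len(self.vocabulary):
            raise ValueError("matrix shape inconsistent with vocabulary/doc_ids")
        col_nonzero = np.asarray((self.matrix != 0).sum(axis=0)).ravel()
        if v and (col_nonzero == 0).any():
            raise ValueError("vocabulary contains all-zero columns")

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def vectorize(docs: Sequence[TokenDoc], mode: str = "tfidf") -> DocTermMatrix:
    """Build a count or tf-idf matrix from cleaned token documents.

    The tf-idf variant is the smoothed one, idf = ln((1+n)/(1+df)) + 1,
    followed by per-document L2 normalization.
    """
    if mode not in ("count", "tfidf"):
        raise ValueError(f"mode must be 'count' or 'tfidf', got {mode!r}")
    if not docs or all(not d.tokens for d in docs):
        raise ValueError("need at least one nonempty document")
    cv = CountVectorizer(analyzer=lambda toks: toks, lowercase=False)
    counts = cv.fit_transform([list(d.tokens) for d in docs])
    if counts.shape[1] == 0:
        raise ValueError("empty vocabulary after preprocessing")
    vocab = cv.get_feature_names_out().tolist()
    if mode == "count":
        mat = sp.csr_matrix(counts)
    else:
        mat = sp.csr_matrix(
            TfidfTransformer(norm="l2", smooth_idf=True).fit_transform(counts)
        )
    return DocTermMatrix(
        matrix=mat,
        vocabulary=vocab,
        doc_ids=[d.doc_id for d in docs],
        mode=mode,
    )


def save_dtm(dtm: DocTermMatrix, prefix: str | Path) -> None:
    """Write MTX matrix plus vocabulary/doc-id sidecar text files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mmwrite(str(prefix.with_suffix(".mtx")), dtm.matrix)
    prefix.with_suffix(".vocab.txt").write_text(
        "\n".join(dtm.vocabulary) + "\n", encoding="utf-8"
    )
    prefix.with_suffix(".docs.txt").write_text(
        "\n".join([dtm.mode] + dtm.doc_ids) + "\n", encoding="utf-8"
    )


def load_dtm(prefix: str | Path) -> DocTermMatrix:
    """Inverse of :func:`save_dtm`."""
    prefix = Path(prefix)
    matrix = sp.csr_matrix(mmread(str(prefix.with_suffix(".mtx"))))
    vocab = prefix.with_suffix(".vocab.txt").read_text(encoding="utf-8").split("\n")
    vocab = [v for v in vocab if v]
    doc_lines = [
        l
        for l in prefix.with_suffix(".docs.txt").read_text(encoding="utf-8").split("\n")
        if l
    ]
    return DocTermMatrix(
        matrix=matrix, vocabulary=vocab, doc_ids=doc_lines[1:], mode=doc_lines[0]
    )
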