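"""Shared fixtures: tiny deterministic corpora generated at test time."""

import warnings

import numpy as np
import pytest

from nephrotext.corpus_io import RawReport, segment_corpus
from nephrotext.preprocess import PreprocessConfig, TokenDoc, preprocess_text
from nephrotext.synth_corpus import SynthSpec, generate

# sklearn emits convergence chatter on deliberately tiny fits
warnings.filterwarnings("ignore", message=".*did not converge.*")
warnings.filterwarnings("ignore", message=".*Stochastic Optimizer.*")


@pytest.fixture(scope="session")
def plain_config() -> PreprocessConfig:
    return PreprocessConfig()


@pytest.fixture
def tagged_report() -> RawReport:
    return RawReport(
        id="r1",
        text=(
            "Klinische Angaben: Hypertonie seit Jahren\n"
            "Mikroskopie:\nNierenrinde mit 18 Glomeruli, keine Nekrosen.\n"
            "Beurteilung:\nMilde Arteriosklerose, kein Anhalt für Glomerulonephritis.\n"
        ),
    )


def make_token_docs(groups: list[int], words_per_group: int = 6,
                    tokens_per_doc: int = 20, seed: int = 0) -> list[TokenDoc]:
    """Disjoint-vocabulary documents, one vocabulary slice per group."""
    rng = np.random.default_rng(seed)
    docs = []
    for i, g in enumerate(groups):
        vocab = [f"g{g}w{j}" for j in range(words_per_group)]
        toks = [vocab[rng.integers(0, words_per_group)] for _ in range(tokens_per_doc)]
        docs.append(TokenDoc(doc_id=f"d{i}", tokens=tuple(toks)))
    return docs


@pytest.fixture(scope="session")
def separable_corpus():
    """Fully separable synthetic corpus (overlap 0, no nuisance signals)."""
    spec = SynthSpec(seed=42, K=4, sizes=(30,) * 4, overlap=0.0, coupling=1.0,
                     malformed_fraction=0.0, outlier_fraction=0.0,
                     author_token_rate=0.0, author_cluster_bias=0.0)
    raws, truth = generate(spec)
    corpus = segment_corpus(raws)
    cfg = PreprocessConfig()
    diag = [preprocess_text(r.id, r.diagnosis, cfg) for r in corpus.reports]
    desc = [preprocess_text(r.id, r.microscopy, cfg) for r in corpus.reports]
    return spec, corpus, truth, diag, desc
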