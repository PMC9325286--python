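"""Synthetic section-tagged report corpora with known ground truth.

The real nephropathology corpus is withheld for privacy, so every stage of
the pipeline is exercised on generated corpora that emulate its structure:
reports carry the German section headers ("Klinische Angaben",
"Mikroskopie", "Beurteilung"); documents come from K planted diagnostic
groups with group-specific vocabularies in both the diagnosis and the
description section; group sizes follow a power law (rare diseases are
rare); each report has an author whose function words colour the text; a
fraction of reports is malformed (a required header is missing) and a
fraction are outliers drawn from background vocabulary only.

Token model, per section token:

    numeric noise            with prob  numeric_noise_rate
    else author function word with prob author_token_rate
    else background term      with prob overlap
    else group-specific term  (marker terms carry extra mass)

``overlap`` therefore dials the difficulty of the clustering stage from
fully separable (0) to indistinguishable (1).  ``coupling`` is the
probability that the description section is drawn from the *same* group as
the diagnosis section; at 0 the description carries no label signal and
any classifier must fall to chance.

Marker terms are synthetic strings ("grp3_diag_m1"), keeping tests
language-neutral; they are alphanumeric on purpose so the number-removal
preprocessing step leaves them alone.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .corpus_io import RawReport

__all__ = ["SynthSpec", "GroundTruth", "generate", "audit", "power_law_sizes",
           "write_truth", "load_truth"]

SECTIONS = ("diag", "desc")


def power_law_sizes(K: int, n_docs: int, exponent: float = 1.5, floor: int = 8) -> list[int]:
    """Group sizes ∝ rank^-exponent, floored, summing exactly to n_docs."""
    w = (np.arange(1, K + 1, dtype=float)) ** (-exponent)
    sizes = np.maximum(np.round(w / w.sum() * n_docs).astype(int), floor)
    sizes[0] += n_docs - sizes.sum()  # absorb rounding in the largest group
    if sizes[0] < floor:
        raise ValueError("n_docs too small for K groups at this floor")
    return sizes.tolist()


@dataclass(frozen=True)
class SynthSpec:
    """Generator configuration; the defaults are the study conditions."""

    K: int = 12
    n_docs: int = 600
    sizes: Optional[tuple[int, ...]] = None     # explicit, else power law
    size_exponent: float = 1.5
    size_floor: int = 8
    vocab_size: int = 2000
    markers_per_group: int = 3
    marker_mass: float = 0.4
    overlap: float = 0.3
    coupling: float = 0.9
    doc_length_mean: tuple[tuple[str, int], ...] = (
        ("clinical", 12), ("desc", 90), ("diag", 45))
    author_count: int = 3
    author_words_per_author: int = 8
    author_token_rate: float = 0.1
    author_cluster_bias: float = 0.3
    numeric_noise_rate: float = 0.05
    malformed_fraction: float = 0.066
    outlier_fraction: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("overlap", "coupling", "author_cluster_bias",
                     "malformed_fraction", "outlier_fraction",
                     "author_token_rate", "numeric_noise_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.sizes is not None:
            if len(self.sizes) != self.K:
                raise ValueError("explicit sizes must list one count per group")
            object.__setattr__(self, "n_docs", int(sum(self.sizes)))
        # vocabulary feasibility: group slices must hold the markers
        if self._slice_size() < self.markers_per_group:
            raise ValueError("vocab too small for the requested markers per group")

    def _slice_size(self) -> int:
        # 60% of the vocabulary is split into 2*K group-exclusive slices
        return int(0.6 * self.vocab_size) // (2 * self.K)

    @property
    def group_sizes(self) -> list[int]:
        if self.sizes is not None:
            return list(self.sizes)
        return power_law_sizes(self.K, self.n_docs, self.size_exponent, self.size_floor)

    @property
    def lengths(self) -> dict[str, int]:
        return dict(self.doc_length_mean)


@dataclass
class GroundTruth:
    """Per-document planted labels, aligned with the generated reports."""

    group: np.ndarray              # diagnosis group, -1 for outliers
    desc_group: np.ndarray         # group the description was drawn from
    author: list[str]
    is_outlier: np.ndarray
    is_malformed: np.ndarray


def _zipf(n: int) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1)
    return w / w.sum()


class _Vocab:
    """Deterministic vocabulary layout and per-group term distributions."""

    def __init__(self, spec: SynthSpec):
        self.spec = spec
        s = spec._slice_size()
        self.group_terms: dict[tuple[str, int], list[str]] = {}
        self.group_probs: dict[tuple[str, int], np.ndarray] = {}
        for sec in SECTIONS:
            for g in range(spec.K):
                markers = [f"grp{g}_{sec}_m{j}" for j in range(spec.markers_per_group)]
                fillers = [f"grp{g}_{sec}_t{j}" for j in range(s - spec.markers_per_group)]
                terms = markers + fillers
                p = np.zeros(len(terms))
                p[: len(markers)] = spec.marker_mass / len(markers)
                if fillers:
                    p[len(markers):] = (1 - spec.marker_mass) * _zipf(len(fillers))
                else:
                    p[: len(markers)] = 1.0 / len(markers)
                self.group_terms[(sec, g)] = terms
                self.group_probs[(sec, g)] = p / p.sum()
        n_bg = spec.vocab_size - 2 * spec.K * s
        self.background = [f"bg_t{j}" for j in range(max(n_bg, 50))]
        self.bg_probs = _zipf(len(self.background))
        self.author_words = {
            f"author_{a}": [f"auth{a}_w{j}" for j in range(spec.author_words_per_author)]
            for a in range(spec.author_count)
        }

    def marker_terms(self, sec: str, g: int) -> list[str]:
        return self.group_terms[(sec, g)][: self.spec.markers_per_group]


def _numeric_token(rng: np.random.Generator) -> str:
    kind = rng.integers(0, 3)
    if kind == 0:
        return str(rng.integers(1, 2030))
    if kind == 1:
        return f"{rng.integers(1, 100)}%"
    return f"{rng.integers(1, 29)}.{rng.integers(1, 13)}.{rng.integers(2015, 2023)}"


def _section_tokens(
    rng: np.random.Generator, vocab: _Vocab, spec: SynthSpec,
    sec: str, group: int, author: str, n_tokens: int, outlier: bool,
) -> list[str]:
    out: list[str] = []
    gterms = None if outlier else vocab.group_terms[(sec, group)]
    gprobs = None if outlier else vocab.group_probs[(sec, group)]
    for _ in range(n_tokens):
        u = rng.random()
        if u < spec.numeric_noise_rate:
            out.append(_numeric_token(rng))
        elif u < spec.numeric_noise_rate + spec.author_token_rate:
            out.append(vocab.author_words[author][rng.integers(0, spec.author_words_per_author)])
        elif outlier or rng.random() < spec.overlap:
            out.append(vocab.background[rng.choice(len(vocab.background), p=vocab.bg_probs)])
        else:
            out.append(gterms[rng.choice(len(gterms), p=gprobs)])
    return out


def _wrap(tokens: Sequence[str], per_line: int = 12) -> str:
    lines = [" ".join(tokens[i : i + per_line]) for i in range(0, len(tokens), per_line)]
    return "\n".join(lines)


def generate(spec: SynthSpec) -> tuple[list[RawReport], GroundTruth]:
    """Generate raw tagged reports plus their ground truth; seed-reproducible."""
    rng = np.random.default_rng(spec.seed)
    vocab = _Vocab(spec)
    sizes = spec.group_sizes
    groups = np.repeat(np.arange(spec.K), sizes)
    rng.shuffle(groups)
    n = groups.size

    is_outlier = rng.random(n) < spec.outlier_fraction
    is_malformed = rng.random(n) < spec.malformed_fraction
    group = np.where(is_outlier, -1, groups)

    authors: list[str] = []
    for g in groups:
        if rng.random() < spec.author_cluster_bias:
            a = int(g) % spec.author_count
        else:
            a = int(rng.integers(0, spec.author_count))
        authors.append(f"author_{a}")

    desc_group = groups.copy()
    recouple = rng.random(n) >= spec.coupling
    desc_group[recouple] = rng.integers(0, spec.K, size=int(recouple.sum()))
    desc_group[is_outlier] = -1

    L = spec.lengths
    reports: list[RawReport] = []
    for d in range(n):
        nd = {k: max(3, int(rng.poisson(v))) for k, v in L.items()}
        clin = [vocab.background[rng.choice(len(vocab.background), p=vocab.bg_probs)]
                for _ in range(nd["clinical"])]
        desc = _section_tokens(rng, vocab, spec, "desc", int(desc_group[d]),
                               authors[d], nd["desc"], bool(is_outlier[d]))
        diag = _section_tokens(rng, vocab, spec, "diag", int(groups[d]),
                               authors[d], nd["diag"], bool(is_outlier[d]))
        drop = rng.choice(["microscopy", "diagnosis"]) if is_malformed[d] else None
        parts = [f"Klinische Angaben:\n{_wrap(clin)}"]
        parts.append(_wrap(desc) if drop == "microscopy" else f"Mikroskopie:\n{_wrap(desc)}")
        parts.append(_wrap(diag) if drop == "diagnosis" else f"Beurteilung:\n{_wrap(diag)}")
        reports.append(
            RawReport(id=f"rep_{d:04d}", text="\n".join(parts) + "\n",
                      authors=frozenset([authors[d]]))
        )
    truth = GroundTruth(
        group=group, desc_group=desc_group, author=authors,
        is_outlier=is_outlier, is_malformed=is_malformed,
    )
    return reports, truth


def audit(reports: list[RawReport], truth: GroundTruth, spec: SynthSpec) -> dict:
    """Goodness-of-fit audit of a generated corpus against its spec.

    Checks (i) that per-group diagnosis-marker frequencies are consistent
    with the token model (chi-square, alpha = 0.01, required for >= 95% of
    groups) and (ii) that the malformed and outlier counts fall inside
    their binomial 99% intervals.
    """
    from .corpus_io import segment_report

    n = len(reports)
    p_marker = ((1 - spec.numeric_noise_rate - spec.author_token_rate)
                * (1 - spec.overlap) * spec.marker_mass / spec.markers_per_group)
    vocab = _Vocab(spec)
    gof_pass = 0
    gof_total = 0
    for g in range(spec.K):
        idx = [i for i in range(n)
               if truth.group[i] == g and not truth.is_malformed[i]]
        tokens: list[str] = []
        for i in idx:
            seg = segment_report(reports[i])
            if seg is not None:
                tokens.extend(seg.diagnosis.split())
        if len(tokens) < 50:
            continue
        gof_total += 1
        markers = vocab.marker_terms("diag", g)
        obs = np.array([tokens.count(m) for m in markers] +
                       [len(tokens) - sum(tokens.count(m) for m in markers)])
        exp = np.array([p_marker * len(tokens)] * len(markers) +
                       [(1 - p_marker * len(markers)) * len(tokens)])
        _, pval = stats.chisquare(obs, exp)
        if pval > 0.01:
            gof_pass += 1

    def _binom99(p: float) -> tuple[int, int]:
        lo, hi = stats.binom.interval(0.99, n, p)
        return int(lo), int(hi)

    mal_lo, mal_hi = _binom99(spec.malformed_fraction)
    out_lo, out_hi = _binom99(spec.outlier_fraction)
    n_mal = int(truth.is_malformed.sum())
    n_out = int(truth.is_outlier.sum())
    return {
        "marker_gof_pass_rate": gof_pass / gof_total if gof_total else 1.0,
        "marker_gof_ok": gof_total == 0 or gof_pass / gof_total >= 0.95,
        "n_malformed": n_mal,
        "malformed_in_bounds": mal_lo <= n_mal <= mal_hi,
        "n_outliers": n_out,
        "outliers_in_bounds": out_lo <= n_out <= out_hi,
    }


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["doc", "group", "desc_group", "author", "is_outlier", "is_malformed"])
        for i in range(truth.group.size):
            w.writerow([f"rep_{i:04d}", int(truth.group[i]), int(truth.desc_group[i]),
                        truth.author[i], int(truth.is_outlier[i]),
                        int(truth.is_malformed[i])])


def load_truth(path: str | Path) -> GroundTruth:
    rows = list(csv.reader(Path(path).open(encoding="utf-8"), delimiter="\t"))[1:]
    return GroundTruth(
        group=np.array([int(r[1]) for r in rows]),
        desc_group=np.array([int(r[2]) for r in rows]),
        author=[r[3] for r in rows],
        is_outlier=np.array([bool(int(r[4])) for r in rows]),
        is_malformed=np.array([bool(int(r[5])) for r in rows]),
    )
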