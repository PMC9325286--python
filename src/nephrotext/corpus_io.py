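"""Reading, sectioning and persisting nephropathology report corpora.

A report arrives as one plain-text document whose parts are announced by
German header keywords placed at the start of a line — typically
``Klinische Angaben`` (clinical information), ``Mikroskopie`` (microscopic
description) and ``Beurteilung`` (diagnostic conclusion).  The downstream
pipeline needs exactly two of those parts: the microscopy section (input of
the classification stage) and the diagnosis section (input of the clustering
stage).  Reports from which both cannot be recovered are excluded, and the
exclusion count is carried with the corpus.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

__all__ = [
    "RawReport",
    "SectionedReport",
    "Corpus",
    "DEFAULT_SECTION_TAGS",
    "read_raw",
    "segment_report",
    "segment_corpus",
    "corpus_stats",
    "write_corpus",
    "load_corpus",
]

#: Section role -> ordered list of header keywords that may open the section.
DEFAULT_SECTION_TAGS: dict[str, tuple[str, ...]] = {
    "clinical": ("Klinische Angaben", "Klinik"),
    "microscopy": ("Mikroskopie", "Histologie"),
    "diagnosis": ("Beurteilung", "Diagnose"),
}

_REQUIRED_ROLES = ("microscopy", "diagnosis")


@dataclass(frozen=True)
class RawReport:
    """One unsegmented report as retrieved from an archive."""

    id: str
    text: str
    authors: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("report id must be nonempty")


@dataclass(frozen=True)
class SectionedReport:
    """A report split into its clinical / microscopy / diagnosis sections.

    ``microscopy`` and ``diagnosis`` are guaranteed nonempty; ``clinical``
    is optional because only the former two feed the analysis stages.
    """

    id: str
    microscopy: str
    diagnosis: str
    clinical: Optional[str] = None
    authors: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.microscopy or not self.diagnosis:
            raise ValueError(
                f"report {self.id!r}: microscopy and diagnosis must be nonempty"
            )


@dataclass
class Corpus:
    """Ordered collection of sectioned reports plus the exclusion count."""

    reports: list[SectionedReport] = field(default_factory=list)
    excluded: int = 0

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reports]
        if len(ids) != len(set(ids)):
            raise ValueError("corpus contains duplicate report ids")

    def __len__(self) -> int:
        return len(self.reports)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Corpus):
            return NotImplemented
        return self.reports == other.reports and self.excluded == other.excluded


def read_raw(path: str | Path, format_hint: Optional[str] = None) -> list[RawReport]:
    """Read raw reports from a directory of ``.txt`` files or a JSONL file.

    Parameters
    ----------
    path:
        Directory (one UTF-8 text file per report, filename stem = id) or a
        line-delimited JSON file with fields ``id``, ``text`` and optionally
        ``authors``.
    format_hint:
        ``"dir"`` or ``"jsonl"``; inferred from the path when omitted.
    """
    path = Path(path)
    if format_hint is None:
        format_hint = "dir" if path.is_dir() else "jsonl"
    reports: list[RawReport] = []
    if format_hint == "dir":
        if not path.is_dir():
            raise IOError(f"not a directory: {path}")
        for f in sorted(path.glob("*.txt")):
            reports.append(RawReport(id=f.stem, text=f.read_text(encoding="utf-8")))
    elif format_hint == "jsonl":
        if not path.is_file():
            raise IOError(f"not a file: {path}")
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                if not line.strip():
                    continue
                rec = json.loads(line)
                authors = rec.get("authors")
                reports.append(
                    RawReport(
                        id=str(rec["id"]),
                        text=rec.get("text", ""),
                        authors=frozenset(authors) if authors is not None else None,
                    )
                )
    else:
        raise ValueError(f"unknown format_hint {format_hint!r}")
    ids = [r.id for r in reports]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate report ids in input")
    return reports


def _tag_pattern(
    tags_config: Mapping[str, Sequence[str]]
) -> tuple[re.Pattern[str], dict[str, str]]:
    # Case-insensitive, anchored at line start, optional trailing colon.
    alts = []
    for role, keywords in tags_config.items():
        for kw in keywords:
            alts.append((role, kw))
    # longer keywords first so e.g. "Klinische Angaben" beats "Klinik"
    alts.sort(key=lambda t: -len(t[1]))
    pattern = "|".join(
        f"(?P<r{i}>{re.escape(kw)})" for i, (_, kw) in enumerate(alts)
    )
    rx = re.compile(rf"^[ \t]*(?:{pattern})[ \t]*:?", re.IGNORECASE | re.MULTILINE)
    return rx, {f"r{i}": role for i, (role, _) in enumerate(alts)}


def segment_report(
    report: RawReport,
    tags_config: Mapping[str, Sequence[str]] = DEFAULT_SECTION_TAGS,
) -> Optional[SectionedReport]:
    """Split one report into sections; return ``None`` when it is malformed.

    Matching is case-insensitive and anchored at line starts; the first
    occurrence of a role's tag wins.  The section body is the text between a
    matched tag and the next matched tag (or end of document).  A report
    lacking a nonempty microscopy or diagnosis section is excluded.
    """
    rx, role_by_group = _tag_pattern(tags_config)
    hits: list[tuple[int, int, str]] = []  # (start, body_start, role)
    for m in rx.finditer(report.text):
        role = next(role_by_group[g] for g, v in m.groupdict().items() if v)
        hits.append((m.start(), m.end(), role))
    sections: dict[str, str] = {}
    for i, (_, body_start, role) in enumerate(hits):
        if role in sections:  # first occurrence wins
            continue
        body_end = hits[i + 1][0] if i + 1 < len(hits) else len(report.text)
        sections[role] = report.text[body_start:body_end].strip()
    if any(not sections.get(role) for role in _REQUIRED_ROLES):
        return None
    return SectionedReport(
        id=report.id,
        microscopy=sections["microscopy"],
        diagnosis=sections["diagnosis"],
        clinical=sections.get("clinical") or None,
        authors=report.authors,
    )


def segment_corpus(
    reports: Iterable[RawReport],
    tags_config: Mapping[str, Sequence[str]] = DEFAULT_SECTION_TAGS,
) -> Corpus:
    """Segment every raw report, counting the ones that fail."""
    kept: list[SectionedReport] = []
    excluded = 0
    for rep in reports:
        seg = segment_report(rep, tags_config)
        if seg is None:
            excluded += 1
        else:
            kept.append(seg)
    return Corpus(reports=kept, excluded=excluded)


def corpus_stats(corpus: Corpus) -> dict[str, float]:
    """Whitespace-token counts over microscopy + diagnosis sections."""
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    counts = [
        len(r.microscopy.split()) + len(r.diagnosis.split()) for r in corpus.reports
    ]
    total = int(sum(counts))
    return {
        "n_reports": len(counts),
        "total_words": total,
        "mean_words_per_report": total / len(counts),
    }


def write_corpus(corpus: Corpus, path: str | Path) -> None:
    """Persist a corpus as line-delimited JSON (one record per report)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        fh.write(json.dumps({"_meta": {"excluded": corpus.excluded}}) + "\n")
        for r in corpus.reports:
            rec = {
                "id": r.id,
                "clinical": r.clinical,
                "microscopy": r.microscopy,
                "diagnosis": r.diagnosis,
                "authors": sorted(r.authors) if r.authors is not None else None,
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")


def load_corpus(path: str | Path) -> Corpus:
    """Inverse of :func:`write_corpus`; validates the record schema."""
    path = Path(path)
    reports: list[SectionedReport] = []
    excluded = 0
    with path.open(encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            rec = json.loads(line)
            if "_meta" in rec:
                excluded = int(rec["_meta"].get("excluded", 0))
                continue
            missing = {"id", "microscopy", "diagnosis"} - rec.keys()
            if missing:
                raise ValueError(f"corpus record missing fields: {sorted(missing)}")
            authors = rec.get("authors")
            reports.append(
                SectionedReport(
                    id=rec["id"],
                    microscopy=rec["microscopy"],
                    diagnosis=rec["diagnosis"],
                    clinical=rec.get("clinical"),
                    authors=frozenset(authors) if authors is not None else None,
                )
            )
    return Corpus(reports=reports, excluded=excluded)
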