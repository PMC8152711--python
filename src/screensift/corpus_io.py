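"""Reading, validating and filtering bibliographic citation records.

A *citation* is a title plus (usually) an abstract, optionally carrying the
eligibility decision of the original review team (the reference standard).
Corpora are ordered: every downstream matrix indexes documents in input-file
order, and all logs refer to citations by id, never by row number.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

_TRUE_LABELS = {"1", "true", "yes", "eligible", "include", "included"}
_FALSE_LABELS = {"0", "false", "no", "ineligible", "exclude", "excluded"}


class CorpusFormatError(ValueError):
    """Raised when an input file cannot be parsed in the declared format."""


class CorpusValidationError(ValueError):
    """Raised when parsed records violate corpus invariants (e.g. duplicate ids)."""


@dataclass(frozen=True)
class Citation:
    """A single title/abstract record.

    ``ref_label`` is the reference-standard eligibility decision (1 eligible,
    0 ineligible) when known; ``None`` for unlabelled corpora.
    """

    id: str
    title: str
    abstract: str = ""
    ref_label: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusValidationError("citation id must be a non-empty string")
        if not self.title or not self.title.strip():
            raise CorpusValidationError(f"citation {self.id!r}: title must be non-empty")
        if self.ref_label is not None and self.ref_label not in (0, 1):
            raise CorpusValidationError(
                f"citation {self.id!r}: ref_label must be 0 or 1, got {self.ref_label!r}"
            )

    @property
    def has_abstract(self) -> bool:
        return bool(self.abstract and self.abstract.strip())


class Corpus:
    """An ordered, id-indexed collection of citations."""

    def __init__(self, citations: Iterable[Citation]):
        self._citations: list[Citation] = list(citations)
        self._index: dict[str, int] = {}
        dupes = []
        for i, c in enumerate(self._citations):
            if c.id in self._index:
                dupes.append(c.id)
            self._index[c.id] = i
        if dupes:
            raise CorpusValidationError(f"duplicate citation ids: {sorted(set(dupes))}")

    def __len__(self) -> int:
        return len(self._citations)

    def __iter__(self) -> Iterator[Citation]:
        return iter(self._citations)

    def __contains__(self, cid: str) -> bool:
        return cid in self._index

    def __getitem__(self, cid: str) -> Citation:
        return self._citations[self._index[cid]]

    @property
    def N(self) -> int:
        return len(self._citations)

    @property
    def ids(self) -> list[str]:
        return [c.id for c in self._citations]

    def labels(self) -> dict[str, int]:
        """Reference-standard labels for every labelled citation."""
        return {c.id: c.ref_label for c in self._citations if c.ref_label is not None}

    def eligible_ids(self) -> list[str]:
        return [c.id for c in self._citations if c.ref_label == 1]


def _parse_label(raw: str, cid: str) -> Optional[int]:
    raw = raw.strip().lower()
    if raw == "":
        return None
    if raw in _TRUE_LABELS:
        return 1
    if raw in _FALSE_LABELS:
        return 0
    raise CorpusFormatError(f"citation {cid!r}: unrecognized label value {raw!r}")


def _read_csv(path: Path) -> Corpus:
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CorpusFormatError(f"{path}: not parseable as CSV ({exc})") from exc
    required = {"id", "title", "abstract"}
    missing = required - set(df.columns)
    if missing:
        raise CorpusFormatError(f"{path}: missing required CSV columns {sorted(missing)}")
    citations = []
    for row in df.itertuples(index=False):
        label = _parse_label(getattr(row, "label", ""), row.id) if "label" in df.columns else None
        try:
            citations.append(Citation(id=row.id, title=row.title, abstract=row.abstract, ref_label=label))
        except CorpusValidationError as exc:
            raise CorpusFormatError(f"{path}: bad record id={row.id!r}: {exc}") from exc
    return Corpus(citations)


# RIS tag-value dialects disagree on title/abstract tags; first non-empty wins.
_RIS_TITLE_TAGS = ("TI", "T1")
_RIS_ABSTRACT_TAGS = ("AB", "N2")


def _read_ris(path: Path) -> Corpus:
    records: list[dict[str, list[str]]] = []
    current: dict[str, list[str]] = {}
    in_record = False
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            tag, sep, value = line[:2], line[2:6], line[6:]
            if sep not in ("  - ", "  -") or not tag.strip():
                # continuation line of the previous tag value
                if in_record and current:
                    last_tag = next(reversed(current))
                    current[last_tag][-1] += " " + line.strip()
                    continue
                raise CorpusFormatError(f"{path}:{lineno}: unparseable RIS line {line!r}")
            if tag == "TY":
                if in_record:
                    raise CorpusFormatError(f"{path}:{lineno}: TY inside an open record")
                in_record = True
                current = {}
            elif tag == "ER":
                if not in_record:
                    raise CorpusFormatError(f"{path}:{lineno}: ER without a record")
                records.append(current)
                in_record = False
                current = {}
            else:
                if not in_record:
                    raise CorpusFormatError(f"{path}:{lineno}: tag {tag!r} outside a record")
                current.setdefault(tag, []).append(value.strip())
    if in_record:
        raise CorpusFormatError(f"{path}: unterminated record (missing ER)")

    def first(rec: dict[str, list[str]], tags: Sequence[str]) -> str:
        for t in tags:
            for v in rec.get(t, []):
                if v.strip():
                    return v.strip()
        return ""

    citations = []
    for i, rec in enumerate(records, start=1):
        cid = first(rec, ("ID",)) or f"ris{i:05d}"
        try:
            citations.append(
                Citation(id=cid, title=first(rec, _RIS_TITLE_TAGS), abstract=first(rec, _RIS_ABSTRACT_TAGS))
            )
        except CorpusValidationError as exc:
            raise CorpusFormatError(f"{path}: bad RIS record #{i}: {exc}") from exc
    return Corpus(citations)


def read_citations(path: str | Path, format: Optional[str] = None) -> Corpus:
    """Read a citation file in RIS or CSV format.

    ``format`` is inferred from the file suffix when not given. Duplicate ids
    are rejected; an empty file yields an empty corpus.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        format = "ris" if path.suffix.lower() == ".ris" else "csv"
    if format == "csv":
        if path.stat().st_size == 0:
            return Corpus([])
        return _read_csv(path)
    if format == "ris":
        return _read_ris(path)
    raise ValueError(f"unknown citation format {format!r} (expected 'ris' or 'csv')")


def write_citations_csv(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus to the CSV dialect ``read_citations`` consumes (round-trips)."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "title", "abstract", "label"])
        for c in corpus:
            writer.writerow([c.id, c.title, c.abstract, "" if c.ref_label is None else c.ref_label])


def filter_title_only(corpus: Corpus) -> Corpus:
    """Drop citations that have no abstract (title-only records).

    Whitespace-only abstracts count as absent. Idempotent; the number of
    removed records is logged.
    """
    kept = [c for c in corpus if c.has_abstract]
    removed = corpus.N - len(kept)
    if removed:
        logger.info("filter_title_only: removed %d title-only citation(s) of %d", removed, corpus.N)
    if not kept and corpus.N:
        logger.warning("filter_title_only: all %d citations were title-only", corpus.N)
    return Corpus(kept)


def screening_text(citation: Citation, separator: str = " ") -> str:
    """Combine title and abstract into the text that is screened and mined.

    A sentence terminator is appended to the title when it lacks one so that
    sentence segmentation stays sane downstream. Deterministic.
    """
    if not citation.has_abstract:
        raise ValueError(f"citation {citation.id!r} has no abstract; apply filter_title_only first")
    title = citation.title.strip()
    if title[-1] not in ".!?":
        title += "."
    return title + separator + citation.abstract.strip()
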