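"""Corpus reading/writing and tokenization.

A corpus is an ordered collection of documents, each carrying a unique id,
free text (title + abstract style), and optionally a publication year and a
group label (e.g. a cancer type or a newsgroup category).  Two plain-text
on-disk formats are supported: JSONL (one object per line) and CSV with a
header row.  Field names default to ``id``/``text``/``year``/``group`` and
can be remapped.
"""

from __future__ import annotations

import csv
import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "Document",
    "Corpus",
    "TokenizerConfig",
    "ReadReport",
    "DEFAULT_STOPWORDS",
    "read_corpus",
    "write_corpus",
    "tokenize",
    "write_table",
]

# Compact English stopword list: function words that dominate raw frequency
# counts but carry no topical signal.  User-overridable via TokenizerConfig.
DEFAULT_STOPWORDS = frozenset(
    """a an the and or but if then else of in on at by for with without to
    from into onto over under as is are was were be been being am do does
    did done have has had having will would shall should can could may
    might must not no nor this that these those it its they them their he
    she his her him we us our you your i me my which who whom whose what
    when where why how there here all any both each few more most other
    some such only own same so than too very just about between through
    during before after above below again further once also""".split()
)

_TOKEN_RE = re.compile(r"[a-z0-9]+(?:-[a-z0-9]+)*")
_TOKEN_RE_CASED = re.compile(r"[A-Za-z0-9]+(?:-[A-Za-z0-9]+)*")


@dataclass(frozen=True)
class Document:
    """One literature record: id, raw text, optional year and group label."""

    doc_id: str
    text: str
    year: int | None = None
    group: str | None = None

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")


@dataclass
class Corpus:
    """Ordered document collection with source provenance."""

    documents: list[Document]
    provenance: str = "in-memory"

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise ValueError(f"duplicate doc_id: {doc.doc_id!r}")
            seen.add(doc.doc_id)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]

    def with_year(self) -> "Corpus":
        """Sub-corpus of documents that carry a year (for yearly analyses)."""
        kept = [d for d in self.documents if d.year is not None]
        return Corpus(kept, provenance=self.provenance + "#with_year")


@dataclass(frozen=True)
class TokenizerConfig:
    """Deterministic tokenization settings.

    Tokens are maximal alphanumeric runs; internal hyphens are kept so that
    terms like ``non-small`` or ``her-2`` survive as single tokens.
    """

    lowercase: bool = True
    min_token_length: int = 2
    stopwords: frozenset[str] = DEFAULT_STOPWORDS

    def __post_init__(self) -> None:
        if self.min_token_length < 1:
            raise ValueError("min_token_length must be >= 1")


@dataclass
class ReadReport:
    """Per-read bookkeeping: how many records were kept or dropped and why."""

    kept: int = 0
    dropped: int = 0
    errors: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"kept": self.kept, "dropped": self.dropped, "errors": self.errors}


def tokenize(text: str, config: TokenizerConfig | None = None) -> list[str]:
    """Split raw text into an ordered token list.

    Lowercases (if configured), extracts alphanumeric runs with internal
    hyphens, then drops stopwords and tokens shorter than
    ``min_token_length``.  Deterministic: same text + config, same output.
    """
    config = config or TokenizerConfig()
    if config.lowercase:
        tokens = _TOKEN_RE.findall(text.lower())
    else:
        tokens = _TOKEN_RE_CASED.findall(text)
    return [
        t
        for t in tokens
        if len(t) >= config.min_token_length and t not in config.stopwords
    ]


_DEFAULT_FIELDS = {"doc_id": "id", "text": "text", "year": "year", "group": "group"}


def _record_to_document(
    record: Mapping, fields: Mapping[str, str], lineno: int
) -> Document:
    id_key, text_key = fields["doc_id"], fields["text"]
    if id_key not in record or record[id_key] in (None, ""):
        raise ValueError(f"record {lineno}: missing {id_key!r} field")
    if text_key not in record or record[text_key] is None:
        raise ValueError(f"record {lineno}: missing {text_key!r} field")
    year_raw = record.get(fields["year"])
    year: int | None
    if year_raw in (None, ""):
        year = None
    else:
        try:
            year = int(year_raw)
        except (TypeError, ValueError):
            raise ValueError(f"record {lineno}: non-integer year {year_raw!r}")
    group_raw = record.get(fields["group"])
    group = None if group_raw in (None, "") else str(group_raw)
    return Document(str(record[id_key]), str(record[text_key]), year, group)


def read_corpus(
    path: str | Path,
    format: str = "jsonl",
    *,
    fields: Mapping[str, str] | None = None,
    strict: bool = False,
) -> tuple[Corpus, ReadReport]:
    """Read a corpus from JSONL or CSV.

    Malformed records (missing id/text, bad year, unparsable line) are
    skipped and counted in the report; in ``strict`` mode the first such
    record aborts the read with a ``ValueError``.  Duplicate ids always
    raise, naming the offending id.
    """
    path = Path(path)
    field_map = dict(_DEFAULT_FIELDS)
    if fields:
        field_map.update(fields)
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}; expected 'jsonl' or 'csv'")

    report = ReadReport()
    documents: list[Document] = []
    seen_ids: set[str] = set()

    def add(record: Mapping, lineno: int) -> None:
        try:
            doc = _record_to_document(record, field_map, lineno)
        except ValueError as exc:
            if strict:
                raise
            report.dropped += 1
            report.errors.append(str(exc))
            return
        if doc.doc_id in seen_ids:
            raise ValueError(f"duplicate doc_id: {doc.doc_id!r} (record {lineno})")
        seen_ids.add(doc.doc_id)
        documents.append(doc)
        report.kept += 1

    with path.open("r", encoding="utf-8", newline="") as fh:
        if format == "jsonl":
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    record = json.loads(line)
                except json.JSONDecodeError as exc:
                    if strict:
                        raise ValueError(f"record {lineno}: invalid JSON: {exc}")
                    report.dropped += 1
                    report.errors.append(f"record {lineno}: invalid JSON")
                    continue
                add(record, lineno)
        else:
            reader = csv.DictReader(fh)
            for lineno, record in enumerate(reader, start=2):
                add(record, lineno)

    return Corpus(documents, provenance=f"{path}#{format}"), report


def write_corpus(
    corpus: Corpus,
    path: str | Path,
    format: str = "jsonl",
    *,
    fields: Mapping[str, str] | None = None,
) -> None:
    """Write a corpus back to disk; round-trips exactly through read_corpus."""
    path = Path(path)
    field_map = dict(_DEFAULT_FIELDS)
    if fields:
        field_map.update(fields)
    if format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for doc in corpus:
                record = {field_map["doc_id"]: doc.doc_id, field_map["text"]: doc.text}
                if doc.year is not None:
                    record[field_map["year"]] = doc.year
                if doc.group is not None:
                    record[field_map["group"]] = doc.group
                fh.write(json.dumps(record, ensure_ascii=False) + "\n")
    elif format == "csv":
        header = [field_map[k] for k in ("doc_id", "text", "year", "group")]
        with path.open("w", encoding="utf-8", newline="") as fh:
            writer = csv.writer(fh, quoting=csv.QUOTE_NONNUMERIC)
            writer.writerow(header)
            for doc in corpus:
                writer.writerow(
                    [
                        doc.doc_id,
                        doc.text,
                        "" if doc.year is None else doc.year,
                        "" if doc.group is None else doc.group,
                    ]
                )
    else:
        raise ValueError(f"unknown format {format!r}")


def write_table(rows: Iterable[Mapping], path: str | Path, *, columns: Sequence[str] | None = None) -> None:
    """Write records as UTF-8 CSV with a header row.

    ``columns`` fixes the schema explicitly; otherwise it is taken from the
    first row.  Zero rows with explicit columns yields a header-only file.
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise ValueError("cannot infer schema from zero rows; pass columns=")
        columns = list(rows[0].keys())
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(columns), quoting=csv.QUOTE_NONNUMERIC)
        writer.writeheader()
        for row in rows:
            writer.writerow({c: row.get(c, "") for c in columns})
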