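"""Corpus loading, Markdown stripping and report persistence.

Input corpora are directories of plain-text / Markdown clinical notes.
All metrics downstream operate on ``Document.normalized_text`` — NFC-normalized
Unicode with Markdown syntax stripped — unless the caller opts out, so that
the measured quantities reflect linguistic content rather than markup.
"""

from __future__ import annotations

import csv
import json
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class CorpusError(ValueError):
    """Raised for invalid corpora or unreadable input files."""


# ---------------------------------------------------------------------------
# Markdown stripping
# ---------------------------------------------------------------------------

_CODE_FENCE_RE = re.compile(r"^\s*(```|~~~)")
_HEADING_RE = re.compile(r"^(\s*)#{1,6}\s*", re.MULTILINE)
_IMAGE_RE = re.compile(r"!\[([^\]]*)\]\([^)]*\)")
_LINK_RE = re.compile(r"\[([^\]]*)\]\([^)]*\)")
_EMPHASIS_RE = re.compile(r"(\*{1,3}|_{1,3})(?=\S)(.+?)(?<=\S)\1", re.DOTALL)
_INLINE_CODE_RE = re.compile(r"`([^`]*)`")
_TABLE_SEP_ROW_RE = re.compile(r"^\s*\|?\s*:?-{2,}:?\s*(\|\s*:?-{2,}:?\s*)*\|?\s*$")


def _strip_table_row(line: str) -> str:
    cells = [c.strip() for c in line.strip().strip("|").split("|")]
    return " ".join(c for c in cells if c)


def _strip_pass(text: str) -> str:
    # fenced code blocks: fence lines become blank lines (preserving the
    # blank-line structure) and the enclosed code is dropped entirely
    kept = []
    in_fence = False
    for line in text.split("\n"):
        if _CODE_FENCE_RE.match(line):
            in_fence = not in_fence
            kept.append("")
        elif not in_fence:
            kept.append(line)
    text = "\n".join(kept)
    lines = []
    for line in text.split("\n"):
        if "|" in line:
            if _TABLE_SEP_ROW_RE.match(line):
                continue
            lines.append(_strip_table_row(line))
        else:
            lines.append(line)
    text = "\n".join(lines)
    text = _HEADING_RE.sub(r"\1", text)
    text = _IMAGE_RE.sub(r"\1", text)
    text = _LINK_RE.sub(r"\1", text)
    text = _EMPHASIS_RE.sub(r"\2", text)
    return _INLINE_CODE_RE.sub(r"\1", text)


def strip_markdown(raw_text: str) -> str:
    """Remove Markdown syntax, keeping the human-readable content.

    Headings lose their ``#`` markers, emphasis markers are dropped, link and
    image syntax keeps the link text, code fences disappear, and table rows
    become their cell texts joined by single spaces (separator rows are
    dropped).  Blank-line structure is preserved.  The function is total and
    idempotent: rules are applied repeatedly until a fixed point, which exists
    because every pass can only shorten the text.
    """
    text = raw_text
    while True:
        new = _strip_pass(text)
        if new == text:
            return text
        text = new


def normalize_text(raw_text: str, strip: bool = True) -> str:
    """NFC-normalize ``raw_text``, optionally stripping Markdown first."""
    text = strip_markdown(raw_text) if strip else raw_text
    return unicodedata.normalize("NFC", text)


def count_markdown_tables(raw_text: str) -> int:
    """Count maximal blocks of consecutive pipe rows containing a ``---`` row."""
    n_tables = 0
    in_block = False
    block_has_sep = False
    for line in raw_text.split("\n") + [""]:
        is_pipe_row = "|" in line and line.strip() != ""
        if is_pipe_row:
            if not in_block:
                in_block = True
                block_has_sep = False
            if _TABLE_SEP_ROW_RE.match(line):
                block_has_sep = True
        else:
            if in_block and block_has_sep:
                n_tables += 1
            in_block = False
    return n_tables


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Document:
    """One clinical note.

    ``file_size_bytes`` is the size of the raw on-disk file (0 for documents
    generated in memory); reported downstream in MiB (bytes / 1,048,576).
    """

    id: str
    raw_text: str
    normalized_text: str
    source_path: str = ""
    file_size_bytes: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise CorpusError("Document id must be non-empty")
        if self.file_size_bytes < 0:
            raise CorpusError("file_size_bytes must be >= 0")

    @classmethod
    def from_text(
        cls,
        id: str,
        raw_text: str,
        *,
        source_path: str = "",
        file_size_bytes: int | None = None,
        strip: bool = True,
    ) -> "Document":
        if file_size_bytes is None:
            file_size_bytes = 0
        return cls(
            id=id,
            raw_text=raw_text,
            normalized_text=normalize_text(raw_text, strip=strip),
            source_path=source_path,
            file_size_bytes=file_size_bytes,
        )

    @property
    def size_mb(self) -> float:
        return self.file_size_bytes / 1_048_576


@dataclass(frozen=True)
class Corpus:
    """A labeled, ordered collection of documents with unique ids."""

    label: str
    documents: tuple[Document, ...]

    def __init__(self, label: str, documents: Iterable[Document]):
        docs = tuple(documents)
        if not label:
            raise CorpusError("Corpus label must be non-empty")
        if not docs:
            raise CorpusError(f"empty corpus: {label!r} has no documents")
        ids = [d.id for d in docs]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise CorpusError(f"duplicate document ids in corpus {label!r}: {dup}")
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "documents", docs)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self):
        return iter(self.documents)


def read_corpus(directory: str | Path, pattern: str = "*", label: str = "corpus",
                strip: bool = True) -> Corpus:
    """Load every file in ``directory`` matching ``pattern`` into a Corpus.

    Files are sorted by filename so document order is reproducible.  Document
    ids are the file stems.  Raises :class:`CorpusError` when no file matches
    or a file is not valid UTF-8.
    """
    directory = Path(directory)
    if not directory.is_dir():
        raise CorpusError(f"not a directory: {directory}")
    paths = sorted(p for p in directory.glob(pattern) if p.is_file())
    if not paths:
        raise CorpusError(f"empty corpus: no files in {directory} match {pattern!r}")
    docs = []
    for p in paths:
        try:
            raw = p.read_text(encoding="utf-8")
        except UnicodeDecodeError as exc:
            raise CorpusError(f"file {p} is not valid UTF-8: {exc}") from exc
        docs.append(
            Document.from_text(
                id=p.stem,
                raw_text=raw,
                source_path=str(p),
                file_size_bytes=p.stat().st_size,
                strip=strip,
            )
        )
    return Corpus(label=label, documents=docs)


def write_corpus(corpus: Corpus, directory: str | Path, suffix: str = ".md") -> list[Path]:
    """Write one file per document (raw text); returns the written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for doc in corpus:
        p = directory / f"{doc.id}{suffix}"
        p.write_text(doc.raw_text, encoding="utf-8")
        paths.append(p)
    return paths


# ---------------------------------------------------------------------------
# Metric report persistence
# ---------------------------------------------------------------------------

#: CSV column names for the per-document table: the eight per-document
#: features plus corpus label and document id.
PER_DOC_FEATURES = (
    "Size (MB)",
    "Word Count",
    "Unique Words",
    "Document Length (Chars)",
    "Character Entropy",
    "Word Entropy",
    "Average Pointwise Mutual Information (PMI)",
    "Jensen-Shannon (JS) Distance",
)
PER_DOC_COLUMNS = ("corpus", "id") + PER_DOC_FEATURES


@dataclass
class MetricReport:
    """Machine-readable corpus-comparison report.

    ``per_document_table`` holds one row per document: corpus label, doc id
    and the eight per-document profile features in :data:`PER_DOC_FEATURES`
    order.  ``corpus_rows`` hold the corpus-level metrics as
    (metric name, reference value, synthetic value, U statistic, p-value)
    with ``None`` where a field does not apply.  ``config_echo`` is the full
    parameter set of the run, sufficient to reproduce it.
    """

    per_document_table: list[dict] = field(default_factory=list)
    corpus_rows: list[dict] = field(default_factory=list)
    config_echo: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_document_table": self.per_document_table,
            "corpus_rows": self.corpus_rows,
            "config_echo": self.config_echo,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MetricReport":
        return cls(
            per_document_table=list(d["per_document_table"]),
            corpus_rows=list(d["corpus_rows"]),
            config_echo=dict(d["config_echo"]),
        )

    def corpus_row(self, metric: str) -> dict:
        for row in self.corpus_rows:
            if row["metric"] == metric:
                return row
        raise KeyError(metric)


def write_report(report: MetricReport, out_dir: str | Path) -> dict[str, Path]:
    """Write ``report.json`` and ``per_document_metrics.csv`` under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    json_path = out_dir / "report.json"
    csv_path = out_dir / "per_document_metrics.csv"
    json_path.write_text(
        json.dumps(report.to_dict(), indent=2, ensure_ascii=False) + "\n",
        encoding="utf-8",
    )
    with csv_path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=PER_DOC_COLUMNS)
        writer.writeheader()
        for row in report.per_document_table:
            writer.writerow({k: row.get(k, "") for k in PER_DOC_COLUMNS})
    return {"json": json_path, "csv": csv_path}


def read_report(json_path: str | Path) -> MetricReport:
    """Round-trip companion of :func:`write_report`."""
    data = json.loads(Path(json_path).read_text(encoding="utf-8"))
    return MetricReport.from_dict(data)
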