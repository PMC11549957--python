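"""Labelled report corpora: loading, validation, tokenization, sentence segmentation.

Every downstream stage (token statistics, sentence cover, perplexity
scoring) shares the text conventions defined here:

* ``tokenize`` — lowercase, split on any non-alphanumeric character, drop
  pure-number tokens and single characters.  Target tokens in incident
  reports are ordinary lowercase words; digit runs are record-id noise.
* ``segment_sentences`` — a deterministic rule-based segmenter that splits
  on ``. ! ?`` followed by whitespace, protected by an abbreviation list
  (honorifics, Latinisms) and a single-initial rule.  The segmenter is
  versioned (``SEGMENTER_VERSION``) so cover solutions are reproducible.

No stopword removal is applied: the downstream selection inequality plus
the expert deny-list are responsible for discarding ubiquitous words.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError, InputError

logger = logging.getLogger(__name__)

SEGMENTER_VERSION = "1.0"

#: Words after which a period never ends a sentence (lowercased, no dot).
ABBREVIATIONS = frozenset(
    {
        "dr", "mr", "mrs", "ms", "prof", "rev", "hon", "st", "jr", "sr",
        "vs", "etc", "eg", "ie", "al", "approx", "dept", "fig",
        "capt", "sgt", "lt", "col", "gen",
    }
)

_TOKEN_RE = re.compile(r"[a-z0-9]+")
_BOUNDARY_RE = re.compile(r"[.!?]+(?=\s)")

DEFAULT_COLUMN_MAP = {"report_id": "report_id", "category": "category", "text": "text"}


def tokenize(text: str) -> list[str]:
    """Split ``text`` into analysis tokens.

    Lowercase, split on every non-alphanumeric character (hyphenated drug
    names split into their components), then drop tokens that are purely
    numeric or shorter than two characters.  Deterministic and idempotent
    on its own space-joined output.
    """
    raw = _TOKEN_RE.findall(text.lower())
    return [t for t in raw if len(t) >= 2 and not t.isdigit()]


@dataclass(frozen=True)
class Report:
    """One free-text incident report with its assigned event category."""

    report_id: str
    category: str
    text: str


@dataclass(frozen=True)
class Sentence:
    """A sentence of a report, positioned by ``(report_id, sent_index)``."""

    report_id: str
    sent_index: int
    text: str
    tokens: tuple[str, ...]


@dataclass
class Corpus:
    """A validated collection of reports sharing a finite category set."""

    reports: list[Report]
    _vocabulary: frozenset[str] | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for r in self.reports:
            if r.report_id in seen:
                raise InputError(f"duplicate report_id: {r.report_id!r}")
            seen.add(r.report_id)
            if not r.text.strip():
                raise InputError(f"report {r.report_id!r} has empty text")

    @property
    def categories(self) -> list[str]:
        """Sorted distinct category labels present in the corpus."""
        return sorted({r.category for r in self.reports})

    @property
    def vocabulary(self) -> frozenset[str]:
        """The set of all analysis tokens over every report text."""
        if self._vocabulary is None:
            vocab: set[str] = set()
            for r in self.reports:
                vocab.update(tokenize(r.text))
            self._vocabulary = frozenset(vocab)
        return self._vocabulary

    def reports_in(self, category: str) -> list[Report]:
        return [r for r in self.reports if r.category == category]

    def __len__(self) -> int:
        return len(self.reports)


def _normalize_ws(text: str) -> str:
    return " ".join(text.split())


def segment_sentences(report: Report) -> list[Sentence]:
    """Split a report into sentences.

    Splits after runs of ``. ! ?`` that are followed by whitespace, unless
    the word immediately before the punctuation is a known abbreviation
    ("Dr.", "etc.") or a single letter (an initial, or the tail of
    "e.g.").  Joining the returned sentence texts with single spaces
    reproduces the whitespace-normalized report text, so every character
    of the narrative is preserved.  Always returns at least one sentence.
    """
    text = _normalize_ws(report.text)
    if not text:
        raise InputError(f"report {report.report_id!r} has empty text")
    boundaries: list[int] = []
    for m in _BOUNDARY_RE.finditer(text):
        prev = text[: m.start()]
        last_word = _TOKEN_RE.findall(prev.lower()[-20:])
        if last_word and (last_word[-1] in ABBREVIATIONS or len(last_word[-1]) == 1):
            continue
        boundaries.append(m.end())
    pieces: list[str] = []
    start = 0
    for b in boundaries:
        piece = text[start:b].strip()
        if piece:
            pieces.append(piece)
        start = b
    tail = text[start:].strip()
    if tail:
        pieces.append(tail)
    if not pieces:  # text was pure punctuation
        pieces = [text]
    return [
        Sentence(report.report_id, i, piece, tuple(tokenize(piece)))
        for i, piece in enumerate(pieces)
    ]


def segment_corpus(corpus: Corpus) -> list[Sentence]:
    """Sentence-segment every report, in report order."""
    out: list[Sentence] = []
    for r in corpus.reports:
        out.extend(segment_sentences(r))
    return out


# ---------------------------------------------------------------------------
# readers / writers


def load_corpus(
    path: str | Path,
    format: str | None = None,
    column_map: Mapping[str, str] | None = None,
) -> Corpus:
    """Read a labelled corpus from CSV (RFC 4180, UTF-8) or JSON-lines.

    ``column_map`` maps the canonical field names ``report_id``,
    ``category``, ``text`` to the columns/keys used in the file.  Records
    with empty or whitespace-only text are dropped with a logged count;
    duplicate report ids and files yielding zero valid reports are errors.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"corpus file not found: {path}")
    if format is None:
        format = "jsonl" if path.suffix in {".jsonl", ".ndjson", ".json"} else "csv"
    if format not in {"csv", "jsonl"}:
        raise ConfigurationError(f"unknown corpus format {format!r} (expected csv or jsonl)")
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    records: Iterable[Mapping[str, object]]
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            records = list(csv.DictReader(fh))
    else:
        with path.open(encoding="utf-8") as fh:
            records = [json.loads(line) for line in fh if line.strip()]

    reports: list[Report] = []
    dropped = 0
    for i, rec in enumerate(records):
        for canonical, col in cmap.items():
            if col not in rec:
                raise ConfigurationError(
                    f"record {i}: missing column {col!r} (mapped from {canonical!r})"
                )
        text = str(rec[cmap["text"]] or "")
        if not text.strip():
            dropped += 1
            continue
        reports.append(
            Report(str(rec[cmap["report_id"]]), str(rec[cmap["category"]]), text)
        )
    if dropped:
        logger.warning("dropped %d report(s) with empty text", dropped)
    if not reports:
        raise InputError(f"no valid reports in {path}")
    return Corpus(reports)


def write_corpus_csv(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["report_id", "category", "text"])
        for r in corpus.reports:
            w.writerow([r.report_id, r.category, r.text])


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in corpus.reports:
            fh.write(
                json.dumps(
                    {"report_id": r.report_id, "category": r.category, "text": r.text}
                )
                + "\n"
            )


def write_sentences_jsonl(sentences: Sequence[Sentence], path: str | Path) -> None:
    """Canonical one-object-per-sentence dump of a segmented corpus."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for s in sentences:
            fh.write(
                json.dumps(
                    {
                        "report_id": s.report_id,
                        "sent_index": s.sent_index,
                        "text": s.text,
                        "tokens": list(s.tokens),
                    }
                )
                + "\n"
            )
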