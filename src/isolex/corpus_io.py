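"""Reading, validation, and span-exact segmentation of clinical-note corpora.

A corpus is a flat sequence of de-identified notes (JSONL: one object per
line; or CSV with a header row).  Each note carries the six metadata fields
used throughout the package (subject, note id, note type, author type, date)
plus the free text.  Sentences and tokens are represented purely as character
spans into their parent text, 0-based and half-open, so every downstream
structure can be sliced back out of the original note verbatim.

Sentence segmentation is line-oriented: clinical templates put one checkbox
or prompt per line ("Lonely/Isolated?? No"), so newlines always terminate a
sentence, as do runs of '.' or '!' followed by whitespace.  Question marks do
NOT split, which keeps questionnaire prompt lines intact as single units.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import date as _date
from pathlib import Path
from typing import Iterable, Sequence

logger = logging.getLogger("isolex")

NOTE_TYPES = frozenset(
    {
        "progress",
        "telephone_encounter",
        "plan_of_care",
        "consult",
        "h_and_p",
        "discharge_summary",
        "ed_provider",
        "radiation_oncology",
        "other",
    }
)

CORPUS_FIELDS = ("subject_id", "note_id", "note_type", "author_type", "date", "text")


class CorpusFormatError(ValueError):
    """Raised for malformed corpus files; message includes the record locus."""


@dataclass(frozen=True)
class Note:
    subject_id: str
    note_id: str
    note_type: str
    author_type: str
    date: _date | None
    text: str


@dataclass(frozen=True)
class Sentence:
    """A sentence as a span into its note's text (note-level coordinates)."""

    note_id: str
    index: int
    start: int
    end: int
    text: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("sentence span reversed")


@dataclass(frozen=True)
class Token:
    """A token as a span into its sentence's text (sentence-relative)."""

    start: int
    end: int
    text: str


# --------------------------------------------------------------------------
# corpus readers
# --------------------------------------------------------------------------


def _parse_date(raw: object, locus: str) -> _date | None:
    if raw is None:
        return None
    s = str(raw).strip()
    if not s or s.lower() in {"none", "null", "na"}:
        return None
    try:
        return _date.fromisoformat(s)
    except ValueError as exc:
        raise CorpusFormatError(f"{locus}: unparseable date {s!r}") from exc


def _make_note(rec: dict, locus: str) -> Note:
    missing = [k for k in CORPUS_FIELDS if k not in rec]
    if missing:
        raise CorpusFormatError(f"{locus}: missing field(s) {', '.join(missing)}")
    if rec["text"] is None:
        raise CorpusFormatError(f"{locus}: text field is null (use empty string)")
    note_type = str(rec["note_type"]).strip()
    if note_type not in NOTE_TYPES:
        logger.warning("%s: unknown note_type %r mapped to 'other'", locus, note_type)
        note_type = "other"
    return Note(
        subject_id=str(rec["subject_id"]),
        note_id=str(rec["note_id"]),
        note_type=note_type,
        author_type=str(rec["author_type"]),
        date=_parse_date(rec["date"], locus),
        text=str(rec["text"]),
    )


def read_corpus(path: str | Path, format: str | None = None) -> list[Note]:
    """Read a note corpus from JSONL or CSV.

    ``format`` is inferred from the suffix when not given.  Malformed records
    raise :class:`CorpusFormatError` naming the offending line; duplicate
    note ids are an error.  An empty file yields an empty corpus with a
    logged warning.
    """
    path = Path(path)
    if not path.exists():
        raise CorpusFormatError(f"corpus file not found: {path}")
    if format is None:
        format = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if format not in {"jsonl", "csv"}:
        raise CorpusFormatError(f"unknown corpus format {format!r}")

    notes: list[Note] = []
    seen: set[str] = set()
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                locus = f"{path.name}:{lineno}"
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise CorpusFormatError(f"{locus}: invalid JSON ({exc})") from exc
                if not isinstance(rec, dict):
                    raise CorpusFormatError(f"{locus}: record is not an object")
                notes.append(_make_note(rec, locus))
    else:
        with path.open("r", encoding="utf-8", newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None:
                logger.warning("%s: empty corpus file", path.name)
                return []
            missing = [k for k in CORPUS_FIELDS if k not in reader.fieldnames]
            if missing:
                raise CorpusFormatError(
                    f"{path.name}: header missing column(s) {', '.join(missing)}"
                )
            for rec in reader:
                locus = f"{path.name}:{reader.line_num}"
                notes.append(_make_note(rec, locus))

    for note in notes:
        if note.note_id in seen:
            raise CorpusFormatError(f"duplicate note_id {note.note_id!r}")
        seen.add(note.note_id)
    if not notes:
        logger.warning("%s: empty corpus", path.name)
    logger.info("read %d notes from %s", len(notes), path)
    return notes


def write_corpus_jsonl(notes: Iterable[Note], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for note in notes:
            rec = {
                "subject_id": note.subject_id,
                "note_id": note.note_id,
                "note_type": note.note_type,
                "author_type": note.author_type,
                "date": note.date.isoformat() if note.date else None,
                "text": note.text,
            }
            fh.write(json.dumps(rec) + "\n")


# --------------------------------------------------------------------------
# segmentation and tokenization
# --------------------------------------------------------------------------

# a sentence ends at a run of '.'/'!' followed by whitespace (or line end);
# '?' never splits so that template lines like "Lonely/Isolated?? No" stay whole
_TERMINATOR = re.compile(r"([.!]+)(?=\s|$)")
_TOKEN = re.compile(r"\w+|[^\w\s]")


def _line_spans(text: str) -> list[tuple[int, int]]:
    spans = []
    start = 0
    for i, ch in enumerate(text):
        if ch == "\n":
            spans.append((start, i))
            start = i + 1
    spans.append((start, len(text)))
    return spans


def segment_text(text: str) -> list[tuple[int, int]]:
    """Character spans of sentences in ``text`` (0-based, half-open, trimmed)."""
    out: list[tuple[int, int]] = []
    for ls, le in _line_spans(text):
        line = text[ls:le]
        pos = 0
        for m in _TERMINATOR.finditer(line):
            seg = (pos, m.end(1))
            pos = m.end(1)
            out.append((ls + seg[0], ls + seg[1]))
        if pos < len(line):
            out.append((ls + pos, ls + le - ls))
    trimmed = []
    for s, e in out:
        seg = text[s:e]
        lstrip = len(seg) - len(seg.lstrip())
        rstrip = len(seg) - len(seg.rstrip())
        s2, e2 = s + lstrip, e - rstrip
        if s2 < e2:
            trimmed.append((s2, e2))
    return trimmed


def segment_sentences(note: Note) -> list[Sentence]:
    """Split a note into sentences with exact note-level character offsets."""
    return [
        Sentence(note_id=note.note_id, index=i, start=s, end=e, text=note.text[s:e])
        for i, (s, e) in enumerate(segment_text(note.text))
    ]


def iter_token_spans(text: str) -> list[tuple[int, int]]:
    """Token spans: maximal word-character runs, plus each punctuation char."""
    return [(m.start(), m.end()) for m in _TOKEN.finditer(text)]


def tokenize(sentence: Sentence | str) -> list[Token]:
    """Tokenize a sentence; offsets are sentence-relative and round-trip."""
    text = sentence if isinstance(sentence, str) else sentence.text
    return [Token(s, e, text[s:e]) for s, e in iter_token_spans(text)]
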