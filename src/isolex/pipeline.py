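"""End-to-end extraction: corpus -> mentions -> context decisions -> records.

One :class:`ExtractionRecord` is emitted per mention that survives context
filtering, carrying the six structured elements (subject, matched term,
author type, note id, date, note type) plus the containing sentence as a
snippet.  Aggregation happens at two granularities, mirroring how such
pipelines are evaluated: notes are the unit for prevalence and performance
(a note is positive if it holds at least one surviving mention), while raw
hits feed the term-frequency table.

Percentages are rounded to one decimal, round-half-even.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict, replace
from decimal import ROUND_HALF_EVEN, Decimal
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .context import ContextAnalyzer, ContextConfig, ContextDecision
from .corpus_io import Note, segment_sentences
from .lexicon import Lexicon, MatchRules, compile_lexicon, normalize
from .matcher import CandidateMention, dedupe_overlaps, find_combination_mentions, find_term_mentions

logger = logging.getLogger("isolex")

CSV_COLUMNS = (
    "subject_id",
    "term",
    "snippet",
    "note_id",
    "date",
    "note_type",
    "author_type",
    "span_start",
    "span_end",
    "status_reasons",
)


def round1(numerator: float, denominator: float) -> float | None:
    """Percentage ``100*numerator/denominator`` to one decimal, half-even.

    Returns None (the undefined marker) for a zero denominator.
    """
    if denominator == 0:
        return None
    q = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    return float(q.quantize(Decimal("0.1"), rounding=ROUND_HALF_EVEN))


@dataclass(frozen=True)
class PipelineConfig:
    """Single switchboard for the pipeline.

    ``mode`` selects the detector preset: "improved" (all context detectors)
    or "paper_faithful" (negation with pseudo-negation exceptions only,
    reproducing the published pipeline's behaviour and its documented false
    positives).  ``max_gap`` overrides the lexicon's combination gap when set.
    """

    mode: str = "improved"
    window_pre: int = 5
    window_post: int = 5
    experiencer_window: int = 10
    max_gap: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in {"improved", "paper_faithful"}:
            raise ValueError(f"unknown mode {self.mode!r}")

    def context_config(self) -> ContextConfig:
        base = (
            ContextConfig.paper_faithful()
            if self.mode == "paper_faithful"
            else ContextConfig.improved()
        )
        return replace(
            base,
            window_pre=self.window_pre,
            window_post=self.window_post,
            experiencer_window=self.experiencer_window,
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(**doc)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")


@dataclass(frozen=True)
class ExtractionRecord:
    subject_id: str
    term: str  # matched surface text
    snippet: str  # the sentence containing the hit
    note_id: str
    date: str | None
    note_type: str
    author_type: str
    span_start: int
    span_end: int
    rule_id: str
    kind: str
    status_reasons: str = ""


@dataclass(frozen=True)
class PrevalenceSummary:
    n_patients: int
    n_positive_patients: int
    patient_pct: float | None
    n_notes: int
    n_positive_notes: int
    mention_count: int
    note_type_counts: dict
    author_type_counts: dict
    term_frequencies: dict  # canonical/rule -> {"hits": int, "percentage": float}

    def to_dict(self) -> dict:
        return asdict(self)


def _canonical_for(lexicon: Lexicon, rule_id: str, surface: str) -> str:
    try:
        return lexicon.term_by_id(rule_id).canonical
    except KeyError:
        return normalize(surface)  # combination patterns report their surface


def run(
    corpus: Sequence[Note],
    lexicon: Lexicon,
    config: PipelineConfig | None = None,
    rules: MatchRules | None = None,
) -> tuple[list[ExtractionRecord], PrevalenceSummary]:
    """Extract surviving mentions from every note and summarize.

    Deterministic for fixed inputs and config.  Notes with empty text are
    counted in denominators but contribute no mentions.
    """
    config = config or PipelineConfig()
    if config.max_gap is not None:
        lexicon = replace(
            lexicon,
            patterns=tuple(replace(p, max_gap=config.max_gap) for p in lexicon.patterns),
        )
    rules = rules if rules is not None else compile_lexicon(lexicon)
    analyzer = ContextAnalyzer(lexicon, rules, config.context_config())

    records: list[ExtractionRecord] = []
    n_candidates = 0
    n_excluded = 0
    for note in corpus:
        if not note.text:
            logger.info("note %s has empty text; skipped", note.note_id)
            continue
        for sentence in segment_sentences(note):
            mentions = find_term_mentions(sentence, rules)
            mentions += find_combination_mentions(sentence, rules.patterns)
            for mention in dedupe_overlaps(mentions):
                n_candidates += 1
                decision = analyzer.analyze(mention, sentence)
                if decision.status != "positive":
                    n_excluded += 1
                    continue
                records.append(
                    ExtractionRecord(
                        subject_id=note.subject_id,
                        term=mention.surface,
                        snippet=sentence.text,
                        note_id=note.note_id,
                        date=note.date.isoformat() if note.date else None,
                        note_type=note.note_type,
                        author_type=note.author_type,
                        span_start=mention.start,
                        span_end=mention.end,
                        rule_id=mention.rule_id,
                        kind=mention.kind,
                        status_reasons=";".join(decision.reasons),
                    )
                )
    logger.info(
        "pipeline: %d candidate mentions, %d excluded by context, %d retained",
        n_candidates,
        n_excluded,
        len(records),
    )
    return records, prevalence(records, corpus, lexicon)


def term_frequency(
    records: Sequence[ExtractionRecord], lexicon: Lexicon | None = None
) -> pd.DataFrame:
    """Hit counts per canonical term with percentages of total hits.

    Order-invariant: rows are sorted by descending count then term.
    """
    counts: dict[str, int] = {}
    for r in records:
        key = _canonical_for(lexicon, r.rule_id, r.term) if lexicon else r.rule_id
        counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    rows = [
        {"term": term, "hits": hits, "percentage": round1(hits, total)}
        for term, hits in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows, columns=["term", "hits", "percentage"])


def prevalence(
    records: Sequence[ExtractionRecord],
    corpus: Sequence[Note],
    lexicon: Lexicon | None = None,
) -> PrevalenceSummary:
    """Note- and patient-level positivity plus the term-frequency table.

    A patient is positive iff any of their notes is; a note is positive iff
    it retains at least one mention.
    """
    patients = {n.subject_id for n in corpus}
    positive_patients = {r.subject_id for r in records}
    positive_notes = {r.note_id for r in records}
    note_type_counts: dict[str, int] = {}
    author_type_counts: dict[str, int] = {}
    by_note = {n.note_id: n for n in corpus}
    for nid in positive_notes:
        note = by_note.get(nid)
        if note is None:
            continue
        note_type_counts[note.note_type] = note_type_counts.get(note.note_type, 0) + 1
        author_type_counts[note.author_type] = (
            author_type_counts.get(note.author_type, 0) + 1
        )
    freq = term_frequency(records, lexicon)
    return PrevalenceSummary(
        n_patients=len(patients),
        n_positive_patients=len(positive_patients),
        patient_pct=round1(len(positive_patients), len(patients)),
        n_notes=len(corpus),
        n_positive_notes=len(positive_notes),
        mention_count=len(records),
        note_type_counts=dict(sorted(note_type_counts.items())),
        author_type_counts=dict(sorted(author_type_counts.items())),
        term_frequencies={
            row.term: {"hits": int(row.hits), "percentage": row.percentage}
            for row in freq.itertuples()
        },
    )


def write_records_csv(records: Iterable[ExtractionRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {col: getattr(r, col) for col in CSV_COLUMNS}
            for r in records
        ],
        columns=list(CSV_COLUMNS),
    )
    df.to_csv(path, index=False)


def read_records_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"subject_id": str, "note_id": str})
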