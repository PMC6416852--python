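"""Candidate mention detection in sentences.

Two mention sources: lexicon terms (via the compiled token trie) and
modifier->anchor->object combination patterns (e.g. "questionable family
support", "loss of ... social ... network").  Both are anchored at token
boundaries — "isolated" never fires inside "isolatedly" — and both feed one
shared overlap-resolution stage, because several surface strings ("lack of
social support") are simultaneously a term and a pattern instance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_io import Sentence, Token, tokenize
from .lexicon import CombinationPattern, MatchRules, normalize


@dataclass(frozen=True)
class CandidateMention:
    """A matched span in note-level character coordinates (0-based half-open)."""

    note_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    rule_id: str
    kind: str  # "term" | "combination"

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)

    def overlaps(self, other: "CandidateMention") -> bool:
        return self.start < other.end and other.start < self.end


def _norm_token_texts(tokens: Sequence[Token]) -> list[str]:
    return [normalize(t.text) for t in tokens]


def find_term_mentions(sentence: Sentence, rules: MatchRules) -> list[CandidateMention]:
    """All term matches in a sentence, pre-dedup (nested matches included)."""
    tokens = tokenize(sentence)
    norm = _norm_token_texts(tokens)
    out = []
    for i, j, rule_id in rules.scan(norm):
        start = sentence.start + tokens[i].start
        end = sentence.start + tokens[j - 1].end
        out.append(
            CandidateMention(
                note_id=sentence.note_id,
                sentence_index=sentence.index,
                start=start,
                end=end,
                surface=sentence.text[tokens[i].start : tokens[j - 1].end],
                rule_id=rule_id,
                kind="term",
            )
        )
    return out


def _phrase_positions(norm: Sequence[str], phrase: str) -> list[tuple[int, int]]:
    """Token-index spans where a (possibly multiword) phrase occurs."""
    words = phrase.split()
    n = len(words)
    return [
        (i, i + n)
        for i in range(len(norm) - n + 1)
        if list(norm[i : i + n]) == words
    ]


def find_combination_mentions(
    sentence: Sentence, patterns: Iterable[CombinationPattern]
) -> list[CandidateMention]:
    """Matches requiring modifier -> anchor -> object order within the
    sentence, with at most ``max_gap`` intervening tokens at each junction
    (punctuation tokens count).  The mention span runs from the first
    modifier token through the object token."""
    tokens = tokenize(sentence)
    norm = _norm_token_texts(tokens)
    out = []
    for pattern in patterns:
        anchors = _phrase_positions(norm, pattern.anchor)
        if not anchors:
            continue
        mod_spans = []
        for modifier in pattern.modifiers:
            mod_spans.extend(_phrase_positions(norm, modifier))
        obj_spans = []
        for obj in pattern.objects:
            obj_spans.extend(_phrase_positions(norm, obj))
        for ms, me in mod_spans:
            for as_, ae in anchors:
                if not (0 <= as_ - me <= pattern.max_gap):
                    continue
                for os_, oe in obj_spans:
                    if not (0 <= os_ - ae <= pattern.max_gap):
                        continue
                    start = sentence.start + tokens[ms].start
                    end = sentence.start + tokens[oe - 1].end
                    out.append(
                        CandidateMention(
                            note_id=sentence.note_id,
                            sentence_index=sentence.index,
                            start=start,
                            end=end,
                            surface=sentence.text[
                                tokens[ms].start : tokens[oe - 1].end
                            ],
                            rule_id=pattern.pattern_id,
                            kind="combination",
                        )
                    )
    return out


def _priority(m: CandidateMention) -> tuple:
    # longest span first; earliest start; term beats combination; stable rule id
    return (-(m.end - m.start), m.start, 0 if m.kind == "term" else 1, m.rule_id)


def dedupe_overlaps(mentions: Sequence[CandidateMention]) -> list[CandidateMention]:
    """Greedy maximal non-overlapping subset: longest span wins, ties broken
    by earliest start, then term over combination.  Exact duplicates keep one."""
    kept: list[CandidateMention] = []
    seen_spans: set[tuple[int, int]] = set()
    for m in sorted(mentions, key=_priority):
        if m.span in seen_spans:
            continue
        if any(m.overlaps(k) for k in kept):
            continue
        kept.append(m)
        seen_spans.add(m.span)
    kept.sort(key=lambda m: (m.start, m.end))
    return kept


def find_candidate_mentions(sentence: Sentence, rules: MatchRules) -> list[CandidateMention]:
    """Term + combination matching with shared overlap resolution."""
    mentions = find_term_mentions(sentence, rules)
    mentions += find_combination_mentions(sentence, rules.patterns)
    return dedupe_overlaps(mentions)
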