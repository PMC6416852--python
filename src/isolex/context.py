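"""Context classification of candidate mentions (NegEx/ConText style).

Each candidate is checked for: negation (with a pseudo-negation exception
list — "but", "is still", "still has", "all family" look like negations in
generic clinical NLP but in practice precede *asserted* social isolation),
a non-patient experiencer ("Pt's wife states ..."), questionnaire answer
templates ("Lonely/Isolated?? No"), group/psychoeducation topics ("... what
HALTS stands for (Hungry Angry Lonely Tired Sick)"), and historical framing.
A mention survives (status "positive") only when none of these fire.

Two operating modes:

* ``paper_faithful`` — negation with the pseudo-negation exceptions only.
  This reproduces the published pipeline's behaviour, including its four
  documented false positives.
* ``improved`` — all detectors on, plus a contrast-discourse rule (a
  contrastive "however"/"but" immediately before the mention clause marks
  the sentence as being about something else, e.g. discharge-care needs).

A trigger whose tokens intersect the mention span never fires: "no" inside
the matched term "no friends" is part of the concept, not a negation of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

from .corpus_io import Sentence, Token, tokenize
from .lexicon import Lexicon, MatchRules, normalize
import re

EXPERIENCERS = ("patient", "family_member", "other_person")

FAMILY_RELATIONS = frozenset(
    {
        "wife", "husband", "mother", "father", "son", "daughter", "sister",
        "brother", "spouse", "grandmother", "grandfather", "aunt", "uncle",
        "cousin", "mom", "dad",
    }
)
POSSESSIVE_PRONOUNS = frozenset({"her", "his", "their", "my"})
REPORTING_VERBS = frozenset(
    {
        "states", "stated", "state", "says", "said", "reports", "reported",
        "report", "notes", "noted", "mentions", "mentioned", "describes",
        "described", "indicates", "indicated",
    }
)
GROUP_TOPIC_CUES = (
    "group",
    "will learn",
    "stands for",
    "topic",
    "education",
    "curriculum",
    "psychoeducation",
    "class",
)
CONTRAST_MARKERS = frozenset({"however", "but"})
NEGATIVE_ANSWERS = frozenset({"no", "none", "denies"})

_ANSWER_LINE = re.compile(
    r"^\s*(?P<prompt>[\w'’ /]+?)\s*(?P<marker>:|\?+|-|—|X)\s*"
    r"(?P<answer>[A-Za-z]+)\s*\.?\s*$"
)


@dataclass(frozen=True)
class ContextConfig:
    """Detector switches and scope windows (token counts, NegEx-style)."""

    window_pre: int = 5
    window_post: int = 5
    experiencer_window: int = 10
    use_negation: bool = True
    use_experiencer: bool = True
    use_answer_template: bool = True
    use_group_topic: bool = True
    use_historical: bool = True
    use_contrast: bool = True

    @classmethod
    def paper_faithful(cls) -> "ContextConfig":
        return cls(
            use_experiencer=False,
            use_answer_template=False,
            use_group_topic=False,
            use_historical=False,
            use_contrast=False,
        )

    @classmethod
    def improved(cls) -> "ContextConfig":
        return cls()


@dataclass(frozen=True)
class ContextDecision:
    mention: object  # CandidateMention
    negated: bool = False
    experiencer: str = "patient"
    answer_negated: bool = False
    group_topic: bool = False
    historical: bool = False
    status: str = "positive"
    reasons: tuple[str, ...] = ()


class ContextAnalyzer:
    """Runs the context detectors for one lexicon + configuration."""

    def __init__(self, lexicon: Lexicon, rules: MatchRules, config: ContextConfig | None = None):
        self.lexicon = lexicon
        self.rules = rules
        self.config = config or ContextConfig()

    # -- shared token machinery -------------------------------------------

    @staticmethod
    def _mention_token_range(mention, sentence: Sentence, tokens: Sequence[Token]):
        """Indices of tokens overlapping the mention span (note coords)."""
        idx = [
            i
            for i, t in enumerate(tokens)
            if sentence.start + t.start < mention.end
            and mention.start < sentence.start + t.end
        ]
        if not idx:
            return (0, 0)
        return (idx[0], idx[-1] + 1)

    @staticmethod
    def _occurrences(norm: Sequence[str], phrase: str) -> list[tuple[int, int]]:
        words = phrase.split()
        n = len(words)
        return [
            (i, i + n)
            for i in range(len(norm) - n + 1)
            if list(norm[i : i + n]) == words
        ]

    def _trigger_fires(
        self,
        occ: tuple[int, int],
        mrange: tuple[int, int],
        position: str,
        window: int,
        blocked: Sequence[tuple[int, int]] = (),
    ) -> bool:
        s, e = occ
        ms, me = mrange
        if s < me and ms < e:  # intersects the mention: never fires
            return False
        for bs, be in blocked:  # swallowed by a pseudo-negation phrase
            if bs <= s and e <= be:
                return False
        if position == "pre":
            return e <= ms and (ms - e) < window
        return s >= me and (s - me) < window

    # -- detectors ---------------------------------------------------------

    def detect_negation(
        self, mention, sentence: Sentence, tokens: Sequence[Token] | None = None
    ) -> tuple[bool, tuple[str, ...]]:
        tokens = tokenize(sentence) if tokens is None else tokens
        norm = [normalize(t.text) for t in tokens]
        mrange = self._mention_token_range(mention, sentence, tokens)
        pseudo_occ: list[tuple[int, int]] = []
        for tr in self.lexicon.triggers_of("pseudo_negation"):
            pseudo_occ.extend(self._occurrences(norm, tr.text))
        reasons = []
        for tr in self.lexicon.triggers_of("negation"):
            for occ in self._occurrences(norm, tr.text):
                if self._trigger_fires(occ, mrange, tr.position, tr.window, pseudo_occ):
                    reasons.append(f"negation:{tr.text}")
                    break
        if self.config.use_contrast:
            for marker in sorted(CONTRAST_MARKERS):
                for occ in self._occurrences(norm, marker):
                    if self._trigger_fires(occ, mrange, "pre", self.config.window_pre):
                        reasons.append(f"contrast:{marker}")
                        break
        return (bool(reasons), tuple(reasons))

    def detect_experiencer(
        self, mention, sentence: Sentence, tokens: Sequence[Token] | None = None
    ) -> str:
        tokens = tokenize(sentence) if tokens is None else tokens
        norm = [normalize(t.text) for t in tokens]
        mrange = self._mention_token_range(mention, sentence, tokens)
        window = self.config.experiencer_window
        # explicit lexicon triggers ("her husband") in the pre window
        for tr in self.lexicon.triggers_of("family_experiencer"):
            for occ in self._occurrences(norm, tr.text):
                if self._trigger_fires(occ, mrange, tr.position, tr.window):
                    return "family_member"
        for i, tok in enumerate(norm):
            if tok not in FAMILY_RELATIONS:
                continue
            if mrange[0] <= i < mrange[1]:
                continue  # relation noun inside the mention itself
            possessive = (
                (i > 0 and norm[i - 1] in POSSESSIVE_PRONOUNS)
                or (i > 1 and norm[i - 1] == "s" and norm[i - 2] in {"'", "’"})
            )
            if possessive and self._trigger_fires((i, i + 1), mrange, "pre", window):
                return "family_member"
            # relation noun governing a reporting clause marks the whole
            # sentence as family-experienced (co-reference is not resolved)
            if any(v in REPORTING_VERBS for v in norm[i + 1 : i + 4]):
                return "family_member"
        return "patient"

    def detect_answer_negation(self, mention, sentence: Sentence) -> bool:
        """True for questionnaire lines: concept prompt(s), a prompt marker
        (':', '?'+, '-', 'X'), then a bare negative answer and nothing else."""
        m = _ANSWER_LINE.match(sentence.text)
        if not m:
            return False
        if normalize(m.group("answer")) not in NEGATIVE_ANSWERS:
            return False
        prompt = m.group("prompt")
        prompt_end = sentence.start + m.end("prompt")
        if mention.start >= prompt_end:
            return False  # mention must sit in the prompt, not the answer
        groups = [g.strip() for g in prompt.split("/") if g.strip()]
        if not groups:
            return False
        term_hit = False
        for g in groups:
            toks = normalize(g).split()
            full = any(j - i == len(toks) for i, j, _ in self.rules.scan(toks))
            if full:
                term_hit = True
            elif len(toks) > 2:
                return False  # a long non-term group means a real clause
        return term_hit

    def detect_group_topic(
        self, mention, sentence: Sentence, tokens: Sequence[Token] | None = None
    ) -> bool:
        tokens = tokenize(sentence) if tokens is None else tokens
        norm = [normalize(t.text) for t in tokens]
        mrange = self._mention_token_range(mention, sentence, tokens)
        for cue in GROUP_TOPIC_CUES:
            for s, e in self._occurrences(norm, cue):
                if not (s < mrange[1] and mrange[0] < e):  # cue outside mention
                    return True
        return False

    def detect_historical(
        self, mention, sentence: Sentence, tokens: Sequence[Token] | None = None
    ) -> tuple[bool, tuple[str, ...]]:
        tokens = tokenize(sentence) if tokens is None else tokens
        norm = [normalize(t.text) for t in tokens]
        mrange = self._mention_token_range(mention, sentence, tokens)
        reasons = []
        for tr in self.lexicon.triggers_of("historical"):
            for occ in self._occurrences(norm, tr.text):
                if self._trigger_fires(occ, mrange, tr.position, tr.window):
                    reasons.append(f"historical:{tr.text}")
                    break
        return (bool(reasons), tuple(reasons))

    # -- orchestration ------------------------------------------------------

    def analyze(self, mention, sentence: Sentence) -> ContextDecision:
        tokens = tokenize(sentence)
        negated, neg_reasons = (False, ())
        if self.config.use_negation:
            negated, neg_reasons = self.detect_negation(mention, sentence, tokens)
        experiencer = "patient"
        if self.config.use_experiencer:
            experiencer = self.detect_experiencer(mention, sentence, tokens)
        answer = self.config.use_answer_template and self.detect_answer_negation(
            mention, sentence
        )
        group = self.config.use_group_topic and self.detect_group_topic(
            mention, sentence, tokens
        )
        historical, hist_reasons = (False, ())
        if self.config.use_historical:
            historical, hist_reasons = self.detect_historical(mention, sentence, tokens)
        return finalize(
            ContextDecision(
                mention=mention,
                negated=negated,
                experiencer=experiencer,
                answer_negated=bool(answer),
                group_topic=bool(group),
                historical=historical,
                reasons=tuple(neg_reasons) + tuple(hist_reasons),
            )
        )


def finalize(partial: ContextDecision) -> ContextDecision:
    """Compute final status from the flags; reasons are completed so that
    they are non-empty exactly when some exclusion flag is set."""
    reasons = list(partial.reasons)
    if partial.experiencer != "patient" and not any(
        r.startswith("experiencer") for r in reasons
    ):
        reasons.append(f"experiencer:{partial.experiencer}")
    if partial.answer_negated and "answer_template:no" not in reasons:
        reasons.append("answer_template:no")
    if partial.group_topic and "group_topic" not in reasons:
        reasons.append("group_topic")
    excluded = (
        partial.negated
        or partial.experiencer != "patient"
        or partial.answer_negated
        or partial.group_topic
        or partial.historical
    )
    if not excluded:
        reasons = []
    return replace(
        partial,
        status="excluded" if excluded else "positive",
        reasons=tuple(reasons),
    )
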