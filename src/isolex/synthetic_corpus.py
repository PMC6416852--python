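"""Synthetic clinical-note corpora with gold labels.

No clinical data ships with this package; the generator emulates the
*statistical structure* of the study corpus — a patient-level prevalence of
social-isolation documentation around 1.2%, mentions clustered within a
positive patient's notes, and a note-type mix dominated by progress notes
and telephone encounters — so the full pipeline and its evaluation can be
exercised end to end.  Filler text is drawn from a fixed non-clinical word
list and every generated note is re-scanned with the compiled lexicon at
generation time, guaranteeing that candidate mentions exist exactly at the
injected gold spans.

Each injected mention is rendered either as a plain patient-experienced
statement or as one of four confounder shapes drawn from the template bank
(negated, family-experienced, questionnaire answer-template, group topic);
the gold label records which.  The generator makes no attempt at realistic
clinical language — passing tests show span bookkeeping and rule logic are
correct under the modeled confounder mix, not that the rules generalize to
real prose.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .corpus_io import Note
from .lexicon import Lexicon, MatchRules, compile_lexicon, default_lexicon
from .matcher import dedupe_overlaps, find_combination_mentions, find_term_mentions
from .corpus_io import segment_sentences

TRUTH_STATUSES = (
    "positive",
    "negated",
    "family_experiencer",
    "template_negated",
    "group_topic",
)

#: note-type mix from the study's training corpus; the progress-note row of
#: the published table is internally inconsistent, so progress absorbs the
#: remainder of the consistent rows.
DEFAULT_NOTE_TYPE_MIX = {
    "progress": 0.522,
    "telephone_encounter": 0.276,
    "plan_of_care": 0.128,
    "consult": 0.025,
    "h_and_p": 0.020,
    "discharge_summary": 0.016,
    "ed_provider": 0.013,
}

AUTHOR_TYPES = ("physician", "social_worker", "nurse_practitioner", "psychologist", "resident")

STUDY_WINDOW = (date(2014, 1, 1), date(2017, 5, 31))

# screened against the lexicon: no term tokens, pattern components, context
# triggers, relation nouns, or group-topic cues appear here
_FILLER_WORDS = (
    "garden", "weather", "morning", "walking", "reading", "coffee", "window",
    "river", "autumn", "bright", "quiet", "gentle", "yellow", "meadow",
    "travel", "music", "painting", "kitchen", "harvest", "evening", "breeze",
    "wooden", "bridge", "lantern", "orchard", "pebble", "copper", "violet",
    "willow", "summer", "stroll", "cottage", "amber", "cedar", "brook",
)


@dataclass(frozen=True)
class CorpusSpec:
    """Generation parameters; defaults mirror the study corpus structure."""

    n_patients: int = 3138
    notes_per_patient: tuple[float, int] = (48.0, 994)  # (mean, max)
    note_type_mix: dict = field(default_factory=lambda: dict(DEFAULT_NOTE_TYPE_MIX))
    patient_prevalence: float = 0.012
    mentions_per_positive_patient: tuple[float, int] = (7.6, 30)  # (mean, max)
    negation_rate: float = 0.05
    family_experiencer_rate: float = 0.05
    template_rate: float = 0.05
    group_topic_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        rates = (
            self.patient_prevalence,
            self.negation_rate,
            self.family_experiencer_rate,
            self.template_rate,
            self.group_topic_rate,
        )
        if any(not 0 <= r <= 1 for r in rates):
            raise ValueError("all rates must lie in [0, 1]")
        if sum(rates[1:]) > 1:
            raise ValueError("confounder rates must sum to <= 1")
        if abs(sum(self.note_type_mix.values()) - 1.0) > 1e-6:
            raise ValueError("note_type_mix must sum to 1")
        if self.notes_per_patient[0] < 1 or self.notes_per_patient[1] < 1:
            raise ValueError("notes_per_patient mean and max must be >= 1")


@dataclass(frozen=True)
class GoldLabel:
    note_id: str
    start: int  # note-level character offsets, 0-based half-open
    end: int
    surface: str
    truth_status: str


# --------------------------------------------------------------------------
# template bank
# --------------------------------------------------------------------------

#: the four published false-positive sentences, kept verbatim as fixtures
TABLE4_SENTENCES = (
    "Lonely/Isolated X Pt’s wife states that she has very little social support from her community.",
    "Patients will learn what HALTS stands for (Hungry Angry Lonely Tired Sick)",
    "Lonely/Isolated?? No",
    "Pt will require 24 h assistance at discharge however questionable family support.",
)

_TEMPLATES = {
    "positive": (
        "Patient endorses {term} at the clinic visit.",
        "He describes {term} since the diagnosis.",
        "She feels {term} most evenings.",
        "Patient reports {term} and poor sleep.",
        "Pt endorses {term} when asked directly.",
    ),
    "negated": (
        "Patient denies {term} today.",
        "He denied {term} at this visit.",
        "Screening negative, denies {term}.",
    ),
    "family_experiencer": (
        "His wife reports {term} at home.",
        "Her husband describes {term} lately.",
        "The daughter states {term} since spring.",
    ),
    "template_negated": (
        "{Term}?? No",
        "{Term}: No",
        "{Term} - Denies",
    ),
    "group_topic": (
        "Patients will learn what the acronym stands for (Hungry Angry {Term} Tired Sick)",
        "Group session today covered {term} and coping.",
        "Education topic: {term} and self-care.",
    ),
}


def template_bank() -> dict[str, tuple[str, ...]]:
    """Parameterized sentence templates per truth-status category, plus the
    four published false-positive sentences verbatim under "table4_fixture"."""
    bank = dict(_TEMPLATES)
    bank["table4_fixture"] = TABLE4_SENTENCES
    return bank


# --------------------------------------------------------------------------
# generation
# --------------------------------------------------------------------------


def _filler_sentence(rng: np.random.Generator) -> str:
    n = int(rng.integers(4, 9))
    words = [str(_FILLER_WORDS[i]) for i in rng.integers(0, len(_FILLER_WORDS), n)]
    words[0] = words[0].capitalize()
    return " ".join(words) + "."


def _mention_surfaces(lexicon: Lexicon) -> list[tuple[str, float]]:
    """Surfaces to inject, weighted by published frequency; includes one
    pure combination-pattern instance so that matching route is exercised."""
    pool = [
        (t.canonical, float(t.table_frequency or 1)) for t in lexicon.terms
    ]
    pool.append(("questionable family support", 5.0))
    return pool


def _draw_category(rng: np.random.Generator, spec: CorpusSpec) -> str:
    u = rng.random()
    edges = (
        ("negated", spec.negation_rate),
        ("family_experiencer", spec.family_experiencer_rate),
        ("template_negated", spec.template_rate),
        ("group_topic", spec.group_topic_rate),
    )
    acc = 0.0
    for name, rate in edges:
        acc += rate
        if u < acc:
            return name
    return "positive"


def _render(rng: np.random.Generator, category: str, surface: str) -> tuple[str, int]:
    """Instantiate a template; returns (sentence, offset of surface)."""
    template = str(_TEMPLATES[category][int(rng.integers(0, len(_TEMPLATES[category])))])
    if "{Term}" in template:
        shown = surface[:1].upper() + surface[1:]
        sentence = template.replace("{Term}", shown)
        return sentence, sentence.index(shown)
    sentence = template.replace("{term}", surface)
    return sentence, sentence.index(surface)


def _verify_note(note: Note, rules: MatchRules, gold_spans: set[tuple[int, int]]) -> None:
    found = set()
    for sentence in segment_sentences(note):
        mentions = find_term_mentions(sentence, rules)
        mentions += find_combination_mentions(sentence, rules.patterns)
        for m in dedupe_overlaps(mentions):
            found.add((m.start, m.end))
    stray = found - gold_spans
    missing = gold_spans - found
    if stray or missing:
        raise RuntimeError(
            f"generated note {note.note_id} leaks lexicon content: "
            f"stray={sorted(stray)} missing={sorted(missing)}"
        )


def generate(
    spec: CorpusSpec | None = None, lexicon: Lexicon | None = None
) -> tuple[list[Note], list[GoldLabel]]:
    """Generate (corpus, gold labels), deterministic for a fixed seed.

    Every injected mention has a gold label with exact note-level offsets;
    every generated note is verified against the compiled lexicon so that
    candidate spans and gold spans coincide exactly.
    """
    spec = spec or CorpusSpec()
    spec.validate()
    lexicon = lexicon or default_lexicon()
    rules = compile_lexicon(lexicon)
    rng = np.random.default_rng(spec.seed)

    note_types = sorted(spec.note_type_mix)
    type_probs = np.array([spec.note_type_mix[t] for t in note_types])
    type_probs = type_probs / type_probs.sum()
    mean_notes, max_notes = spec.notes_per_patient
    mean_mentions, max_mentions = spec.mentions_per_positive_patient
    window_days = (STUDY_WINDOW[1] - STUDY_WINDOW[0]).days

    notes: list[Note] = []
    gold: list[GoldLabel] = []
    surfaces = _mention_surfaces(lexicon)
    surface_texts = [s for s, _ in surfaces]
    surface_weights = np.array([w for _, w in surfaces])
    surface_weights = surface_weights / surface_weights.sum()

    for pi in range(spec.n_patients):
        subject_id = f"p{pi:05d}"
        n_notes = int(min(max_notes, max(1, rng.geometric(1.0 / mean_notes))))
        # each note starts as a list of filler sentences
        note_sentences: list[list[str]] = []
        note_meta = []
        for ni in range(n_notes):
            k = int(rng.integers(1, 4))
            note_sentences.append([_filler_sentence(rng) for _ in range(k)])
            nt = str(note_types[int(rng.choice(len(note_types), p=type_probs))])
            author = str(AUTHOR_TYPES[int(rng.integers(0, len(AUTHOR_TYPES)))])
            d = STUDY_WINDOW[0] + timedelta(days=int(rng.integers(0, window_days + 1)))
            note_meta.append((nt, author, d))

        injections: list[list[tuple[str, str]]] = [[] for _ in range(n_notes)]
        if rng.random() < spec.patient_prevalence:
            k = int(min(max_mentions, max(1, 1 + rng.poisson(max(mean_mentions - 1, 0)))))
            for _ in range(k):
                target = int(rng.integers(0, n_notes))
                surface = str(
                    surface_texts[int(rng.choice(len(surface_texts), p=surface_weights))]
                )
                category = _draw_category(rng, spec)
                injections[target].append((surface, category))

        for ni in range(n_notes):
            note_id = f"{subject_id}-n{ni:04d}"
            sentences = list(note_sentences[ni])
            placed: list[tuple[int, str, int, str]] = []  # (sentence idx, surface, off, cat)
            for surface, category in injections[ni]:
                sentence, offset = _render(rng, category, surface)
                pos = int(rng.integers(0, len(sentences) + 1))
                sentences.insert(pos, sentence)
                placed = [
                    (si + 1 if si >= pos else si, s, o, c) for si, s, o, c in placed
                ]
                # record the rendered surface (template may capitalize it)
                placed.append((pos, sentence[offset : offset + len(surface)], offset, category))
            text = "\n".join(sentences)
            starts = []
            acc = 0
            for s in sentences:
                starts.append(acc)
                acc += len(s) + 1
            nt, author, d = note_meta[ni]
            note = Note(
                subject_id=subject_id,
                note_id=note_id,
                note_type=nt,
                author_type=author,
                date=d,
                text=text,
            )
            spans = set()
            for si, shown, offset, category in placed:
                start = starts[si] + offset
                end = start + len(shown)
                gold.append(
                    GoldLabel(
                        note_id=note_id,
                        start=start,
                        end=end,
                        surface=shown,
                        truth_status=category,
                    )
                )
                spans.add((start, end))
            _verify_note(note, rules, spans)
            notes.append(note)
    return notes, gold


def write_gold_csv(gold: Sequence[GoldLabel], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "note_id": g.note_id,
                "span_start": g.start,
                "span_end": g.end,
                "surface": g.surface,
                "truth_status": g.truth_status,
            }
            for g in gold
        ],
        columns=["note_id", "span_start", "span_end", "surface", "truth_status"],
    ).to_csv(path, index=False)
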