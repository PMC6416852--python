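"""The social-isolation lexicon: terms, combination patterns, context triggers.

The packaged default lexicon transcribes the published 24-row term table of a
prostate-cancer clinical-note study of social isolation.  Case-variant rows
("Lonely" vs "lonely") collapse to a single canonical entry whose recorded
surfaces keep both printed forms, giving 20 canonical terms for the 24 printed
rows; both counts are exposed.  "live alone" is deliberately absent — it is
frequent in clinical notes but does not by itself indicate social isolation —
and any lexicon file containing it is rejected at load time.

Matching is case-insensitive after Unicode NFKC normalization.  Compilation
produces a token-sequence trie so a sentence is scanned once for all variants
of all terms, anchored at token boundaries; the trie is required (and tested)
to be extensionally equal to a naive per-variant scan.
"""

from __future__ import annotations

import io
import json
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .corpus_io import iter_token_spans

TRIGGER_KINDS = frozenset({"negation", "pseudo_negation", "family_experiencer", "historical"})
TERM_SOURCES = frozenset({"seed", "expert_added", "corpus_discovered"})

#: number of term rows in the published frequency table (case-sensitive surfaces)
TABLE2_N_ROWS = 24
#: total hits across the published frequency table
TABLE2_TOTAL_HITS = 266


class LexiconError(ValueError):
    """Raised when a lexicon file violates the schema or an invariant."""


def normalize(text: str) -> str:
    """Canonical text form used for all matching: NFKC then casefold to lower."""
    return unicodedata.normalize("NFKC", text).lower()


def _norm_tokens(text: str) -> tuple[str, ...]:
    norm = normalize(text)
    return tuple(norm[s:e] for s, e in iter_token_spans(norm))


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TermEntry:
    entry_id: str
    canonical: str
    variants: frozenset[str]
    source: str
    table_surfaces: tuple[str, ...] = ()
    table_frequency: int | None = None

    def validate(self) -> None:
        if not self.canonical.strip():
            raise LexiconError(f"term {self.entry_id}: empty canonical")
        if self.source not in TERM_SOURCES:
            raise LexiconError(f"term {self.entry_id}: bad source {self.source!r}")
        norm_variants = {normalize(v) for v in self.variants}
        if normalize(self.canonical) not in norm_variants:
            raise LexiconError(f"term {self.entry_id}: canonical not among variants")
        for surface in set(self.variants) | {self.canonical}:
            if normalize(surface) == "live alone":
                raise LexiconError(
                    f"term {self.entry_id}: 'live alone' is excluded from the lexicon "
                    "(it does not by itself indicate social isolation)"
                )


@dataclass(frozen=True)
class CombinationPattern:
    """Modifier -> anchor -> object phrase pattern, gap-bounded, one sentence.

    ``max_gap`` bounds the count of intervening tokens at each junction;
    punctuation tokens count toward the gap.
    """

    pattern_id: str
    modifiers: frozenset[str]
    anchor: str
    objects: frozenset[str]
    max_gap: int = 3
    suspect_modifiers: frozenset[str] = frozenset()

    def validate(self) -> None:
        if not (self.modifiers and self.anchor.strip() and self.objects):
            raise LexiconError(f"pattern {self.pattern_id}: empty component set")
        if self.max_gap < 0:
            raise LexiconError(f"pattern {self.pattern_id}: negative max_gap")
        if not self.suspect_modifiers <= {normalize(m) for m in self.modifiers}:
            raise LexiconError(f"pattern {self.pattern_id}: suspect modifier not a modifier")


@dataclass(frozen=True)
class ContextTrigger:
    text: str
    position: str  # "pre" | "post"
    kind: str  # negation | pseudo_negation | family_experiencer | historical
    window: int = 5

    def validate(self) -> None:
        if not self.text.strip():
            raise LexiconError("trigger with empty text")
        if self.position not in {"pre", "post"}:
            raise LexiconError(f"trigger {self.text!r}: bad position {self.position!r}")
        if self.kind not in TRIGGER_KINDS:
            raise LexiconError(f"trigger {self.text!r}: bad kind {self.kind!r}")
        if self.window < 1:
            raise LexiconError(f"trigger {self.text!r}: window must be >= 1")


@dataclass(frozen=True)
class Lexicon:
    terms: tuple[TermEntry, ...]
    patterns: tuple[CombinationPattern, ...]
    triggers: tuple[ContextTrigger, ...]
    version: str = "unversioned"

    def validate(self) -> None:
        ids = [t.entry_id for t in self.terms]
        if len(ids) != len(set(ids)):
            raise LexiconError("duplicate entry_id in lexicon")
        canon = [normalize(t.canonical) for t in self.terms]
        dupes = {c for c in canon if canon.count(c) > 1}
        if dupes:
            raise LexiconError(f"duplicate canonical term(s): {sorted(dupes)}")
        for t in self.terms:
            t.validate()
        pids = [p.pattern_id for p in self.patterns]
        if len(pids) != len(set(pids)):
            raise LexiconError("duplicate pattern_id in lexicon")
        for p in self.patterns:
            p.validate()
        seen: set[tuple[str, str, str]] = set()
        for tr in self.triggers:
            tr.validate()
            key = (normalize(tr.text), tr.position, tr.kind)
            if key in seen:
                raise LexiconError(f"trigger {tr.text!r} repeated for ({tr.position}, {tr.kind})")
            seen.add(key)

    # -- convenience views -------------------------------------------------

    @property
    def n_canonical_terms(self) -> int:
        return len(self.terms)

    @property
    def n_table_rows(self) -> int:
        """Count of printed table rows backing the terms (24 in the default)."""
        return sum(max(len(t.table_surfaces), 1) for t in self.terms)

    def term_by_id(self, entry_id: str) -> TermEntry:
        for t in self.terms:
            if t.entry_id == entry_id:
                return t
        raise KeyError(entry_id)

    def rule_ids(self) -> frozenset[str]:
        return frozenset(t.entry_id for t in self.terms) | frozenset(
            p.pattern_id for p in self.patterns
        )

    def triggers_of(self, kind: str, position: str | None = None) -> tuple[ContextTrigger, ...]:
        return tuple(
            tr
            for tr in self.triggers
            if tr.kind == kind and (position is None or tr.position == position)
        )


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------


def _data_path(name: str) -> Path:
    return Path(str(resources.files("isolex").joinpath("data", name)))


def load_lexicon(path: str | Path) -> Lexicon:
    """Load and validate a lexicon from its flat-JSON file format."""
    path = Path(path)
    if not path.exists():
        raise LexiconError(f"lexicon file not found: {path}")
    raw = path.read_text(encoding="utf-8")
    if not raw.strip():
        raise LexiconError(f"{path.name}: empty lexicon file")
    try:
        doc = json.loads(raw)
    except json.JSONDecodeError as exc:
        raise LexiconError(f"{path.name}: invalid JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise LexiconError(f"{path.name}: top level must be an object")
    for key in ("terms", "patterns", "triggers"):
        if key not in doc or not isinstance(doc[key], list):
            raise LexiconError(f"{path.name}: missing or non-array section {key!r}")
    try:
        terms = tuple(
            TermEntry(
                entry_id=str(t["entry_id"]),
                canonical=normalize(str(t["canonical"])),
                variants=frozenset(str(v) for v in t["variants"]),
                source=str(t.get("source", "corpus_discovered")),
                table_surfaces=tuple(str(s) for s in t.get("table_surfaces", ())),
                table_frequency=t.get("table_frequency"),
            )
            for t in doc["terms"]
        )
        patterns = tuple(
            CombinationPattern(
                pattern_id=str(p["pattern_id"]),
                modifiers=frozenset(normalize(str(m)) for m in p["modifiers"]),
                anchor=normalize(str(p["anchor"])),
                objects=frozenset(normalize(str(o)) for o in p["objects"]),
                max_gap=int(p.get("max_gap", 3)),
                suspect_modifiers=frozenset(
                    normalize(str(m)) for m in p.get("suspect_modifiers", ())
                ),
            )
            for p in doc["patterns"]
        )
        triggers = tuple(
            ContextTrigger(
                text=normalize(str(tr["text"])),
                position=str(tr["position"]),
                kind=str(tr["kind"]),
                window=int(tr.get("window", 5)),
            )
            for tr in doc["triggers"]
        )
    except (KeyError, TypeError) as exc:
        raise LexiconError(f"{path.name}: schema violation ({exc!r})") from exc
    lex = Lexicon(
        terms=terms,
        patterns=patterns,
        triggers=triggers,
        version=str(doc.get("version", "unversioned")),
    )
    lex.validate()
    return lex


def default_lexicon() -> Lexicon:
    """The packaged social-isolation lexicon (24 printed rows, 20 canonicals)."""
    return load_lexicon(_data_path("default_lexicon.json"))


def load_table2_frequencies() -> pd.DataFrame:
    """The published term-frequency table as printed: 24 rows summing to 266."""
    return pd.read_csv(_data_path("table2_frequencies.tsv"), sep="\t")


def load_table2_prenegations() -> pd.DataFrame:
    """The published pre-negation column: 8 distinct case-sensitive strings."""
    return pd.read_csv(_data_path("table2_prenegations.tsv"), sep="\t")


# --------------------------------------------------------------------------
# variant expansion
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VariantRules:
    """Fixed suffix-rule morphology plus case variation.

    A closed stand-in for a stemmer: each surface word maps to a stem by
    stripping one suffix (with i->y restoration), and a stem regenerates its
    whole family.  Only the last word of a multiword term inflects; words in
    the adverb table additionally alternate with their -ly form anywhere.
    """

    suffixes: tuple[str, ...] = ("ness", "ings", "ions", "ing", "ion", "ed", "es", "s", "e")
    adverb_pairs: Mapping[str, str] = field(
        default_factory=lambda: {"social": "socially"}
    )
    irregular: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {"withdraw": ("withdrawn", "withdrawal")}
    )
    case_variants: bool = True

    def stem(self, word: str) -> str:
        w = normalize(word)
        for base, forms in self.irregular.items():
            if w == base or w in forms:
                return base
        for base, adv in self.adverb_pairs.items():
            if w == adv:
                return base
        for suf in self.suffixes:
            if w.endswith(suf) and len(w) - len(suf) >= 3:
                w = w[: -len(suf)]
                if w.endswith("i"):
                    w = w[:-1] + "y"
                return self.stem(w)
        return w

    def family(self, word: str) -> frozenset[str]:
        stem = self.stem(word)
        cands = {stem, stem + "e", stem + "ed", stem + "ing", stem + "ion",
                 stem + "ness", stem + "s", stem + "es"}
        if stem.endswith("e"):
            cands |= {stem + "d", stem[:-1] + "ing", stem[:-1] + "ion"}
        if stem.endswith("y"):
            cands |= {stem[:-1] + "iness", stem[:-1] + "ies"}
        cands |= set(self.irregular.get(stem, ()))
        if stem in self.adverb_pairs:
            cands.add(self.adverb_pairs[stem])
        # keep only forms the stemmer maps back, so expansion is stem-closed
        return frozenset(c for c in cands if self.stem(c) == stem)


DEFAULT_VARIANT_RULES = VariantRules()


_RULES_DEFAULT = object()


def expand_variants(entry: TermEntry, rules=_RULES_DEFAULT) -> frozenset[str]:
    """Deterministic surface set for a term: morphology on the final word,
    adverb alternation anywhere, optional first-letter case variants.

    With an empty rule set (``rules=None``) this returns just the canonical.
    Expansion is idempotent: expanding any returned variant yields a subset
    of the result.
    """
    if rules is _RULES_DEFAULT:
        rules = DEFAULT_VARIANT_RULES
    if rules is None:
        return frozenset({entry.canonical})
    words = normalize(entry.canonical).split()
    if not words:
        return frozenset({entry.canonical})
    word_sets: list[frozenset[str]] = []
    for i, w in enumerate(words):
        forms = {w}
        stem = rules.stem(w)
        if stem in rules.adverb_pairs:
            forms |= {stem, rules.adverb_pairs[stem]}
        if i == len(words) - 1:
            forms |= rules.family(w)
        word_sets.append(frozenset(forms))
    out: set[str] = set()
    combos = [""]
    for ws in word_sets:
        combos = [f"{c} {w}".strip() for c in combos for w in sorted(ws)]
    out.update(combos)
    out.add(entry.canonical)
    if rules.case_variants:
        out |= {v[:1].upper() + v[1:] for v in list(out)}
    return frozenset(out)


# --------------------------------------------------------------------------
# compilation: token-sequence trie over all term variants
# --------------------------------------------------------------------------


class MatchRules:
    """Compiled multi-pattern structure over normalized token sequences.

    ``scan`` returns *every* match of every variant anchored at token
    boundaries, including nested and overlapping ones; deduplication is a
    separate downstream stage.  Compilation is deterministic and
    ``serialize`` is byte-stable for equal lexicons.
    """

    def __init__(self, lexicon: Lexicon):
        self.version = lexicon.version
        self.patterns = lexicon.patterns
        self._entries: dict[tuple[str, ...], list[str]] = {}
        for term in sorted(lexicon.terms, key=lambda t: t.entry_id):
            surfaces = set(term.variants) | {term.canonical}
            for surface in surfaces:
                toks = _norm_tokens(surface)
                if not toks:
                    continue
                bucket = self._entries.setdefault(toks, [])
                if term.entry_id not in bucket:
                    bucket.append(term.entry_id)
        self._trie: dict = {}
        for toks, rule_ids in sorted(self._entries.items()):
            node = self._trie
            for tok in toks:
                node = node.setdefault(tok, {})
            node.setdefault(None, []).extend(sorted(rule_ids))

    def scan(self, tokens: Iterable[str]) -> list[tuple[int, int, str]]:
        """All (first_token_idx, last_token_idx_exclusive, rule_id) matches
        over an already-normalized token sequence."""
        toks = list(tokens)
        hits: list[tuple[int, int, str]] = []
        for i in range(len(toks)):
            node = self._trie
            j = i
            while j < len(toks) and toks[j] in node:
                node = node[toks[j]]
                j += 1
                for rule_id in node.get(None, ()):
                    hits.append((i, j, rule_id))
        return hits

    def serialize(self) -> bytes:
        doc = {
            "version": self.version,
            "normalization": "nfkc+lower",
            "entries": [
                {"tokens": list(toks), "rules": rules}
                for toks, rules in sorted(self._entries.items())
            ],
            "patterns": [
                {
                    "pattern_id": p.pattern_id,
                    "modifiers": sorted(p.modifiers),
                    "anchor": p.anchor,
                    "objects": sorted(p.objects),
                    "max_gap": p.max_gap,
                }
                for p in self.patterns
            ],
        }
        return json.dumps(doc, sort_keys=True, separators=(",", ":")).encode("utf-8")


def compile_lexicon(lexicon: Lexicon) -> MatchRules:
    """Compile a validated lexicon into the trie-backed matcher."""
    lexicon.validate()
    return MatchRules(lexicon)
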