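"""Context classification: negation, experiencer, templates, group topics."""

import itertools

import pytest

from isolex import (
    ContextAnalyzer,
    ContextConfig,
    ContextDecision,
    Note,
    finalize,
    find_candidate_mentions,
    segment_sentences,
)
from isolex.synthetic_corpus import TABLE4_SENTENCES


@pytest.fixture(scope="module")
def analyzer(lexicon, rules):
    return ContextAnalyzer(lexicon, rules, ContextConfig.improved())


def _mention_in(text, rules, which=0):
    note = Note("s1", "n1", "progress", "physician", None, text)
    sent = segment_sentences(note)[0]
    mentions = find_candidate_mentions(sent, rules)
    assert mentions, f"no candidate mention in {text!r}"
    return mentions[which], sent


# --------------------------------------------------------------------------
# negation
# --------------------------------------------------------------------------


def test_denies_negates(analyzer, rules):
    m, s = _mention_in("denies loneliness", rules)
    negated, reasons = analyzer.detect_negation(m, s)
    assert negated and any(r.startswith("negation:den") for r in reasons)


def test_trigger_inside_mention_never_fires(analyzer, rules):
    for text in ("he has no friends", "reports no social support", "no family support noted"):
        m, s = _mention_in(text, rules)
        negated, _ = analyzer.detect_negation(m, s)
        assert not negated, text


def test_pseudo_negation_does_not_negate(analyzer, rules):
    m, s = _mention_in("still has no friends", rules)
    negated, _ = analyzer.detect_negation(m, s)
    assert not negated


def test_all_family_is_a_false_negation(analyzer, rules):
    m, s = _mention_in("he is estranged from all family and has no friends", rules)
    negated, _ = analyzer.detect_negation(m, s)
    assert not negated
    assert analyzer.analyze(m, s).status == "positive"


def test_negation_respects_window(analyzer, rules):
    near = _mention_in("not currently lonely", rules)
    far = _mention_in("not one word about the garden or the copper kettle, lonely", rules)
    assert analyzer.detect_negation(*near)[0]
    assert not analyzer.detect_negation(*far)[0]


# --------------------------------------------------------------------------
# experiencer
# --------------------------------------------------------------------------


def test_wife_reporting_clause_marks_family(analyzer, rules):
    m, s = _mention_in(TABLE4_SENTENCES[0], rules)
    assert analyzer.detect_experiencer(m, s) == "family_member"


def test_her_husband_before_mention_marks_family(analyzer, rules):
    m, s = _mention_in("her husband endorses feeling lonely", rules)
    assert analyzer.detect_experiencer(m, s) == "family_member"


def test_patient_report_stays_patient(analyzer, rules):
    m, s = _mention_in("Patient reports loneliness", rules)
    assert analyzer.detect_experiencer(m, s) == "patient"


def test_bare_family_word_is_not_a_relation(analyzer, rules):
    # "family" inside the matched concept must not trip the experiencer rule
    m, s = _mention_in("reports no family support", rules)
    assert analyzer.detect_experiencer(m, s) == "patient"


# --------------------------------------------------------------------------
# answer-template negation
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "line,expected",
    [
        ("Lonely/Isolated?? No", True),
        ("Lonely/Isolated?? Yes", False),
        ("Loneliness: None", True),
        ("Lonely - Denies", True),
        ("Lonely at times; no acute distress.", False),
    ],
)
def test_answer_template_lines(analyzer, rules, line, expected):
    m, s = _mention_in(line, rules)
    assert analyzer.detect_answer_negation(m, s) is expected


def test_answer_grammar_by_enumeration(analyzer, rules):
    """Enumerate the template grammar: prompt x marker x answer x trailer.
    The rule must fire exactly for bare negative answers with no trailer."""
    negatives = {"No", "None", "Denies"}
    for prompt, marker, answer, trailer in itertools.product(
        ("Lonely", "Lonely/Isolated", "Social isolation"),
        (":", "?", "??", "-"),
        ("No", "None", "Denies", "Yes", "Present"),
        ("", " and garden walking daily"),
    ):
        line = f"{prompt}{marker} {answer}{trailer}"
        m, s = _mention_in(line, rules)
        expected = answer in negatives and trailer == ""
        assert analyzer.detect_answer_negation(m, s) is expected, line


# --------------------------------------------------------------------------
# group topic
# --------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        (TABLE4_SENTENCES[1], True),
        ("Patient endorses feeling lonely", False),
        ("Group session today; topic: loneliness and coping", True),
    ],
)
def test_group_topic_cues(analyzer, rules, text, expected):
    m, s = _mention_in(text, rules)
    assert analyzer.detect_group_topic(m, s) is expected


# --------------------------------------------------------------------------
# finalize and mode behaviour
# --------------------------------------------------------------------------


def test_all_flags_false_is_positive():
    d = finalize(ContextDecision(mention=None))
    assert d.status == "positive" and d.reasons == ()


def test_family_experiencer_alone_excludes():
    d = finalize(ContextDecision(mention=None, experiencer="family_member"))
    assert d.status == "excluded"
    assert any("experiencer" in r for r in d.reasons)


def test_exclusion_is_monotone():
    base = dict(negated=False, answer_negated=False, group_topic=False, historical=False)
    for flags in itertools.product([False, True], repeat=4):
        kw = dict(zip(base, flags))
        d = finalize(ContextDecision(mention=None, **kw))
        assert (d.status == "excluded") == any(flags)
        # setting one more flag never flips excluded -> positive
        for key in kw:
            d2 = finalize(ContextDecision(mention=None, **{**kw, key: True}))
            if d.status == "excluded":
                assert d2.status == "excluded"


def test_reasons_nonempty_iff_excluded(analyzer, rules):
    for text in (
        "Patient endorses feeling lonely",
        "denies loneliness",
        *TABLE4_SENTENCES,
    ):
        m, s = _mention_in(text, rules)
        d = analyzer.analyze(m, s)
        assert (d.status == "excluded") == bool(d.reasons)


def test_table4_regression_paper_faithful_vs_improved(lexicon, rules):
    """The four published false-positive sentences all survive the
    paper-faithful detector set and are all excluded by the improved one."""
    faithful = ContextAnalyzer(lexicon, rules, ContextConfig.paper_faithful())
    improved = ContextAnalyzer(lexicon, rules, ContextConfig.improved())
    for text in TABLE4_SENTENCES:
        m, s = _mention_in(text, rules)
        assert faithful.analyze(m, s).status == "positive", text
        assert improved.analyze(m, s).status == "excluded", text


def test_historical_trigger_excludes(analyzer, rules):
    m, s = _mention_in("history of loneliness", rules)
    d = analyzer.analyze(m, s)
    assert d.historical and d.status == "excluded"


def test_detectors_commute(lexicon, rules):
    """Each detector reads only the sentence, so the combined decision equals
    recombining independently computed flags."""
    analyzer = ContextAnalyzer(lexicon, rules, ContextConfig.improved())
    for text in (*TABLE4_SENTENCES, "denies loneliness", "Patient endorses feeling lonely"):
        m, s = _mention_in(text, rules)
        d = analyzer.analyze(m, s)
        negated, neg_r = analyzer.detect_negation(m, s)
        hist, hist_r = analyzer.detect_historical(m, s)
        rebuilt = finalize(
            ContextDecision(
                mention=m,
                negated=negated,
                experiencer=analyzer.detect_experiencer(m, s),
                answer_negated=analyzer.detect_answer_negation(m, s),
                group_topic=analyzer.detect_group_topic(m, s),
                historical=hist,
                reasons=neg_r + hist_r,
            )
        )
        assert rebuilt == d
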