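import random

import pytest
from hypothesis import HealthCheck, settings

from isolex import compile_lexicon, default_lexicon
from isolex.corpus_io import iter_token_spans
from isolex.lexicon import normalize

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


@pytest.fixture(scope="session")
def rules(lexicon):
    return compile_lexicon(lexicon)


def naive_scan(text_tokens, lexicon):
    """Independent oracle: scan each term variant separately at token
    boundaries over a normalized token sequence; returns the same
    (start, end, rule_id) triples the compiled trie must produce."""
    norm = list(text_tokens)
    hits = set()
    for term in lexicon.terms:
        for surface in set(term.variants) | {term.canonical}:
            s = normalize(surface)
            words = [s[a:b] for a, b in iter_token_spans(s)]
            k = len(words)
            if k == 0:
                continue
            for i in range(len(norm) - k + 1):
                if norm[i : i + k] == words:
                    hits.add((i, i + k, term.entry_id))
    return hits


@pytest.fixture(scope="session")
def random_sentences():
    """1,000 reproducible synthetic sentences, some with injected terms."""
    rng = random.Random(20240901)
    fillers = (
        "alpha bravo charlie delta echo foxtrot golf hotel india juliet "
        "kilo mike november oscar papa quebec romeo sierra tango uniform"
    ).split()
    injectables = [
        "lonely", "loneliness", "no friends", "social isolation",
        "lack of social support", "socially isolated", "isolation and loneliness",
        "feels isolated", "limited social network", "questionable family support",
        "no social support",
    ]
    sentences = []
    for _ in range(1000):
        n = rng.randint(3, 12)
        words = [rng.choice(fillers) for _ in range(n)]
        inserted = []
        for _ in range(rng.randint(0, 2)):
            term = rng.choice(injectables)
            pos = rng.randint(0, len(words))
            words.insert(pos, term)
            inserted.append(term)
        sentences.append((" ".join(words), inserted))
    return sentences
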