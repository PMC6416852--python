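{
  "version": "social-isolation-1.0",
  "terms": [
    {"entry_id": "t01", "canonical": "lack of social support", "variants": ["lack of social support"], "source": "corpus_discovered", "table_surfaces": ["lack of social support"], "table_frequency": 52},
    {"entry_id": "t02", "canonical": "lonely", "variants": ["lonely", "Lonely"], "source": "seed", "table_surfaces": ["lonely", "Lonely"], "table_frequency": 47},
    {"entry_id": "t03", "canonical": "no friends", "variants": ["no friends", "no friend"], "source": "expert_added", "table_surfaces": ["no friends"], "table_frequency": 35},
    {"entry_id": "t04", "canonical": "loneliness", "variants": ["loneliness", "Loneliness"], "source": "seed", "table_surfaces": ["loneliness", "Loneliness"], "table_frequency": 33},
    {"entry_id": "t05", "canonical": "social withdraw", "variants": ["social withdraw", "Social withdraw", "social withdrawal"], "source": "expert_added", "table_surfaces": ["Social withdraw"], "table_frequency": 26},
    {"entry_id": "t06", "canonical": "socially isolated", "variants": ["socially isolated"], "source": "corpus_discovered", "table_surfaces": ["socially isolated"], "table_frequency": 22},
    {"entry_id": "t07", "canonical": "social isolation", "variants": ["social isolation", "Social isolation"], "source": "corpus_discovered", "table_surfaces": ["social isolation", "Social isolation"], "table_frequency": 11},
    {"entry_id": "t08", "canonical": "feels isolated", "variants": ["feels isolated"], "source": "corpus_discovered", "table_surfaces": ["feels isolated"], "table_frequency": 8},
    {"entry_id": "t09", "canonical": "lack of social supports", "variants": ["lack of social supports"], "source": "corpus_discovered", "table_surfaces": ["lack of social supports"], "table_frequency": 6},
    {"entry_id": "t10", "canonical": "no social support", "variants": ["no social support"], "source": "corpus_discovered", "table_surfaces": ["no social support"], "table_frequency": 5},
    {"entry_id": "t11", "canonical": "limited social support", "variants": ["limited social support", "Limited social support"], "source": "corpus_discovered", "table_surfaces": ["Limited social support", "Limited social support"], "table_frequency": 5},
    {"entry_id": "t12", "canonical": "feel isolated", "variants": ["feel isolated"], "source": "seed", "table_surfaces": ["feel isolated"], "table_frequency": 3},
    {"entry_id": "t13", "canonical": "no family support", "variants": ["no family support"], "source": "corpus_discovered", "table_surfaces": ["no family support"], "table_frequency": 3},
    {"entry_id": "t14", "canonical": "isolation and loneliness", "variants": ["isolation and loneliness"], "source": "corpus_discovered", "table_surfaces": ["isolation and loneliness"], "table_frequency": 2},
    {"entry_id": "t15", "canonical": "socially withdrawn", "variants": ["socially withdrawn", "Socially withdrawn"], "source": "corpus_discovered", "table_surfaces": ["Socially withdrawn"], "table_frequency": 2},
    {"entry_id": "t16", "canonical": "socially isolating", "variants": ["socially isolating"], "source": "corpus_discovered", "table_surfaces": ["socially isolating"], "table_frequency": 2},
    {"entry_id": "t17", "canonical": "limited social connection", "variants": ["limited social connection", "limited social connections"], "source": "corpus_discovered", "table_surfaces": ["limited social connection"], "table_frequency": 1},
    {"entry_id": "t18", "canonical": "limited social network", "variants": ["limited social network", "Limited social network"], "source": "corpus_discovered", "table_surfaces": ["Limited social network"], "table_frequency": 1},
    {"entry_id": "t19", "canonical": "lack in social support", "variants": ["lack in social support"], "source": "corpus_discovered", "table_surfaces": ["lack in social support"], "table_frequency": 1},
    {"entry_id": "t20", "canonical": "loss of social network", "variants": ["loss of social network"], "source": "corpus_discovered", "table_surfaces": ["loss of social network"], "table_frequency": 1}
  ],
  "patterns": [
    {
      "pattern_id": "family_support_combo",
      "modifiers": ["not have reliable", "questionable", "no", "lack"],
      "anchor": "family",
      "objects": ["companionship", "support", "network"],
      "max_gap": 3,
      "suspect_modifiers": []
    },
    {
      "pattern_id": "social_network_combo",
      "modifiers": ["limited", "absence of", "work in increasing", "lack", "loss of", "no"],
      "anchor": "social",
      "objects": ["network", "support", "connection", "contact"],
      "max_gap": 3,
      "suspect_modifiers": ["work in increasing"]
    }
  ],
  "triggers": [
    {"text": "no", "position": "pre", "kind": "negation", "window": 5},
    {"text": "not", "position": "pre", "kind": "negation", "window": 5},
    {"text": "denies", "position": "pre", "kind": "negation", "window": 5},
    {"text": "deny", "position": "pre", "kind": "negation", "window": 5},
    {"text": "denied", "position": "pre", "kind": "negation", "window": 5},
    {"text": "negative", "position": "pre", "kind": "negation", "window": 5},
    {"text": "negative for", "position": "pre", "kind": "negation", "window": 5},
    {"text": "without", "position": "pre", "kind": "negation", "window": 5},
    {"text": "never", "position": "pre", "kind": "negation", "window": 5},
    {"text": "ruled out", "position": "post", "kind": "negation", "window": 5},
    {"text": "unlikely", "position": "post", "kind": "negation", "window": 5},
    {"text": "but", "position": "pre", "kind": "pseudo_negation", "window": 5},
    {"text": "all family", "position": "pre", "kind": "pseudo_negation", "window": 5},
    {"text": "discussed", "position": "pre", "kind": "pseudo_negation", "window": 5},
    {"text": "however", "position": "pre", "kind": "pseudo_negation", "window": 5},
    {"text": "is still", "position": "pre", "kind": "pseudo_negation", "window": 5},
    {"text": "still has", "position": "pre", "kind": "pseudo_negation", "window": 5},
    {"text": "risk", "position": "pre", "kind": "pseudo_negation", "window": 5},
    {"text": "her husband", "position": "pre", "kind": "family_experiencer", "window": 10},
    {"text": "history of", "position": "pre", "kind": "historical", "window": 5},
    {"text": "in the past", "position": "post", "kind": "historical", "window": 5},
    {"text": "years ago", "position": "post", "kind": "historical", "window": 5}
  ]
}
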