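# Methods

## The extraction model

`isolex` treats social-isolation detection as lexicon-driven mention
extraction followed by rule-based context classification — the same
architecture as NegEx/ConText-era clinical IE systems. The model's core
assumptions are:

* Social isolation, when documented at all, is expressed through a small,
  stable vocabulary ("lonely", "no friends", "lack of social support") or
  through short modifier–anchor–object constructions ("questionable family
  support", "loss of … social … network"). Matching is therefore exact at
  token boundaries after NFKC + lowercase normalization; no fuzzy matching,
  embeddings, or spelling correction.
* Whether a mention *asserts* patient-experienced isolation is decidable
  from the containing sentence alone: negation, experiencer, template
  answers, group topics, and historical framing are all sentence-local
  phenomena. Cross-sentence co-reference ("she" after "Pt's wife") is
  deliberately not resolved.
* Clinical notes are line-oriented: questionnaire templates put one prompt
  per line, so newlines terminate sentences, as do runs of `.`/`!` followed
  by whitespace. `?` never splits — "Lonely/Isolated?? No" must survive as
  one unit for the answer-template rule to see it. The cost is that
  mid-sentence abbreviations ("Dr. Smith") over-split; none of the context
  rules depend on joining across such splits.

All spans are 0-based half-open character offsets into the parent text, and
every structure (sentence, token, mention, gold label) round-trips by
slicing. This single convention is enforced by property tests.

## The lexicon

The packaged lexicon transcribes the published 24-row term-frequency table
(266 total hits). Case-variant rows ("Lonely"/"lonely") and one duplicated
surface ("Limited social support", printed twice with 3 and 2 hits —
plausibly a lost lowercase variant) collapse to 20 canonical entries; both
counts (24 printed rows, 20 canonicals) are exposed. The source prose cites
slightly different leading counts than the table; the table is internally
consistent (its frequency column sums to 266) and is taken as authoritative.

"live alone" is excluded by design — it is common in notes but does not by
itself indicate social isolation — and lexicon validation rejects any file
containing it, so the exclusion survives lexicon editing.

Two combination patterns ship: *{not have reliable, questionable, no, lack}
→ family → {companionship, support, network}* and *{limited, absence of,
work in increasing, lack, loss of, no} → social → {network, support,
connection, contact}*. The modifier "work in increasing" is kept verbatim
for fidelity but flagged `suspect` in the resource, as it reads like a
transcription artifact. `max_gap` defaults to 3 tokens per junction
(punctuation counts): large enough for "lack of social support" and "loss
of his social network", small enough to block long-range joins like
"limited resources … social ties … support network". Components must occur
in modifier→anchor→object order within one sentence.

Morphologic variants use a fixed suffix-rule table
(-e/-ed/-ing/-ion/-ness/-s with i↔y restoration, "social"↔"socially", an
irregular map for withdraw/withdrawn/withdrawal) rather than a stemmer.
The rule set is *stem-closed*: every generated form strips back to the same
stem, which makes expansion idempotent and lets an independent
suffix-stripping oracle verify it. Overgenerated forms ("isolats") are
harmless — they never occur in text — and keep the generator simple.

Compilation builds a token-sequence trie over all variants of all terms.
The trie is pure plumbing: its contract, enforced by test, is extensional
equality with a naive per-variant scan, and its serialization is
byte-deterministic.

## Context rules

* **Negation** — trigger vocabulary (no, not, denies, without, …) with a
  5-token pre/post window inside the sentence (the NegEx convention; the
  source system's window is not documented, so the field default is used).
  Two protections matter: a trigger whose tokens lie inside the mention
  span never fires ("no" in "no friends" is part of the concept), and a
  pseudo-negation list — "but", "But", "all family", "Discussed",
  "However", "is still", "still has", plus "risk" — never negates. The
  pseudo list reproduces the documented finding that of the eight
  pre-negation strings co-occurring with these terms, only "her husband"
  truly changes the assertion (by changing the experiencer), while the
  others precede *asserted* isolation.
* **Experiencer** — a family-relation noun (wife, husband, daughter, …)
  marks the mention family-experienced when it is possessive-marked within
  a 10-token pre-window ("her husband", "Pt's wife") or governs a reporting
  verb anywhere in the sentence ("wife states …"). The second clause is a
  sentence-level approximation: it is what allows
  "Lonely/Isolated X Pt's wife states that she has very little social
  support…" to be excluded even though the relation noun follows the
  matched prompt token. The bare word "family" is *not* a relation cue —
  it appears inside positive concepts ("no family support").
* **Answer-template negation** — a line consisting of concept prompts
  (each ≤ 2 tokens or itself a lexicon term, separated by "/"), a prompt
  marker (`:`, `?`+, `-`, `X`), and a bare negative answer (No/None/Denies)
  with no further clause. "Lonely at times; no acute distress." fails the
  grammar (the "no" opens a clause), as required.
* **Group topic** — cue vocabulary (group, will learn, stands for, topic,
  education, curriculum, …) co-occurring in the sentence outside the
  mention; covers acronym expansions like "(Hungry Angry Lonely Tired
  Sick)".
* **Historical** — a minimal trigger list (history of; in the past; years
  ago), since the category is named in the source design but no rules are
  documented.

### Modes

`paper_faithful` runs negation (with the pseudo exceptions) only; on the
four documented false-positive sentences all four candidates survive,
reproducing the published behaviour. `improved` runs every detector and
additionally a **contrast-discourse rule**: a contrastive marker
("however"/"but") immediately preceding the mention clause, outside the
mention span, excludes it. This rule is this package's own design choice.
None of the five named detector categories covers the fourth documented
false positive ("Pt will require 24 h assistance at discharge however
questionable family support." — a sentence about care needs, not the
patient's social state); the contrastive marker is the only surface signal
available without parsing, so improved mode uses it. The trade-off is
explicit: a genuine "… but he feels lonely" would also be excluded in
improved mode, which is why the rule is not part of the faithful preset and
why the pseudo-negation semantics ("but" never *negates*) are unchanged in
both modes.

Exclusion is monotone (a flag can only remove, never add, a positive), and
detectors are independent, so decisions are order-free.

## Evaluation machinery

Counting is note-level: a note is positive if it retains ≥ 1 mention.
Precision/recall/F are exposed at full precision and in a rounded reporting
style (P and R rounded to two decimals first, F computed from the rounded
values) because chart-review reports are conventionally printed that way —
with counts (36, 4, 1) the two styles give F = 0.935 and 0.93 respectively,
and both are available rather than silently reconciled.

Review sizing uses Cochran's formula with finite-population correction.
The published design states N = 1057, anticipated prevalence 5%, and a 95%
confidence level but omits the margin; d = 0.05 is adopted because it is
the unique standard margin reproducing the printed 69-patient review under
this formula (the infinite-population form gives 73). This reconstruction
is documented rather than silently assumed.

Percentages are rounded to one decimal, round-half-even, as a single stated
rule. Under it 17/1057 → 1.6% reproduces the published evaluation-cohort
prevalence, while 35/3138 → 1.1% does not reproduce the printed 1.2% under
any standard rounding; the discrepancy is documented, not matched.

## Synthetic corpora

The generator emulates the *statistical structure* of the study corpus, not
its language: patient-level prevalence (default 0.012), mentions clustered
within a positive patient's notes (mean 7.6 injected mentions per positive
patient, placed in randomly chosen notes), notes per patient geometric with
mean 48 (capped at 994), note dates uniform over 2014-01-01…2017-05-31, and
a note-type mix taken from the published corpus description (telephone
27.6%, plan of care 12.8%, consults 2.5%, H&P 2.0%, discharge 1.6%, ED
1.3%, progress notes absorbing the remainder — the printed progress-note
row is internally inconsistent, so it is derived, not copied). Injected
surfaces are drawn weighted by published term frequency, plus one pure
combination-pattern instance ("questionable family support") so both
matching routes are exercised.

Confounder rates (fraction of injected mentions rendered as negated,
family-experienced, answer-template, or group-topic sentences) default to
0.05 each. No rates are published; 5% each makes every documented
false-positive shape appear at visible frequency — roughly 20% of injected
mentions confounded, comparable in spirit to the 4 confounded notes among
the 40 the published pipeline flagged — while keeping positives dominant.

Filler text is drawn from a fixed non-clinical word list screened against
the lexicon, trigger vocabularies, relation nouns, and group cues, and
every generated note is re-scanned with the compiled lexicon at generation
time: candidate spans must coincide exactly with injected gold spans or
generation aborts. Consequently, on a confounder-free corpus the pipeline's
span-level precision and recall are exactly 1.0 by construction *if and
only if* the matcher, segmenter, and context rules are correct — which is
the point of the test. Passing says nothing about recall on real clinical
prose, misspellings, section headers, or vocabulary outside the lexicon.

Test and acceptance runs use scaled-down corpora (hundreds of patients, a
few notes each, elevated prevalence around 0.1–0.3 so positives are
plentiful at small n); these sizes are the package's own choice for a fast,
deterministic suite, and the structural parameters above remain at their
study-condition defaults.

## Numerical and degenerate-input choices

* Undefined metrics (zero denominators) are values (`None`), not
  exceptions; percentage of an empty patient set likewise.
* Overlap resolution is greedy under (longest span, earliest start, term
  before combination, rule id) — verified maximal and order-canonical by
  brute force on small sets.
* All randomness flows through `numpy.random.default_rng(seed)`; equal
  seeds give byte-identical corpora and samples.
* Empty notes count in denominators but are skipped for matching; unknown
  note types map to "other" with a warning; duplicate note ids are errors.

## Known limitations

* Whole notes are matched; no section segmentation (mentions in templated
  sections are treated like narrative text).
* The experiencer rule's sentence-level reporting clause can over-exclude
  ("Patient lives with wife, reports loneliness" would be marked
  family-experienced).
* The contrast rule in improved mode trades recall for precision, as
  described above.
* The lexicon was built for one population (older men with prostate
  cancer at a single institution); applying it elsewhere needs
  re-validation, which is why the lexicon is an editable JSON resource
  rather than code.
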