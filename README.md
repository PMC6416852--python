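# isolex

Rule-based extraction of **social isolation** mentions from clinical
narratives.

Social isolation — the perception that one's social relationships are
insufficient in quality or quantity — is a social determinant of health that
is rarely coded in the EHR; when it is documented at all, it is buried in
free-text notes ("he is becoming socially isolated", "questionable family
support", "Lonely/Isolated?? No"). `isolex` implements a lexicon-driven NLP
pipeline that finds such mentions, filters out the ones that are negated,
experienced by a family member, questionnaire artifacts, or
psychoeducation-group topics, and emits structured records suitable for
cohort screening. It is aimed at clinical-informatics researchers studying
social determinants of health who need a transparent, auditable alternative
to black-box classifiers — every extraction is traceable to a lexicon entry
and a context rule.

## Method

A note is split into line-aware sentences with exact character offsets, and
candidate mentions are found by two routes:

1. **Term matching** — a 24-row lexicon (20 canonical terms after case
   collapse: *lonely, loneliness, no friends, lack of social support,
   social isolation, socially isolated, …*) compiled into a token-sequence
   trie; matching is case-insensitive after NFKC normalization and anchored
   at token boundaries.
2. **Combination patterns** — modifier → anchor → object sequences such as
   *{no, lack, questionable, not have reliable} … family … {support,
   companionship, network}*, with at most 3 intervening tokens per junction.

Each candidate then passes through NegEx/ConText-style context detectors:
negation (window of 5 tokens, with a pseudo-negation exception list — "but",
"is still", "still has", "all family" look like negations but in practice
precede *asserted* isolation), experiencer ("Pt's wife states …" is the
wife's isolation, not the patient's), answer-template negation
("Lonely/Isolated?? No"), group-topic detection ("… what HALTS stands for
(Hungry Angry Lonely Tired Sick)"), and historical framing. A mention
survives only if no detector fires. A note is *positive* if it retains at
least one mention; a patient is positive if any of their notes is.

Evaluation follows the chart-review design: note-level precision
TP/(TP+FP), recall TP/(TP+FN), F = 2PR/(P+R), raw percent inter-rater
agreement, and review sizing by Cochran's formula with finite-population
correction,

    n = ceil( N·z²·p(1−p) / ( d²·(N−1) + z²·p(1−p) ) ).

Two pipeline modes are provided: `paper_faithful` (negation filtering only,
reproducing the published pipeline's behaviour including its documented
false positives) and `improved` (all detectors).

## Worked example

No clinical data ships with the package; the synthetic-corpus module
generates labeled note corpora with configurable confounder rates:

```bash
$ cat spec.json
{"n_patients": 200, "notes_per_patient": [3.0, 8], "patient_prevalence": 0.1,
 "mentions_per_positive_patient": [3.0, 6], "seed": 42}

$ isolex simulate --spec spec.json --out corpus.jsonl --gold gold.csv
619 notes, 39 gold labels
$ isolex extract --corpus corpus.jsonl --out mentions.csv --summary summary.json
30 mentions in 21 notes from 16 patients
$ head -2 mentions.csv
subject_id,term,snippet,note_id,date,note_type,author_type,span_start,span_end,status_reasons
p00049,social withdraw,He describes social withdraw since the diagnosis.,p00049-n0000,2015-09-06,plan_of_care,physician,13,28,
```

Of the 39 injected mentions, 30 are plain patient-experienced statements and
are retained; the other 9 were rendered as negated, family-experienced,
answer-template or group-topic confounders and are excluded by the context
detectors (that is what `status_reasons` records). The summary reports 16 of
200 patients positive (`patient_pct: 8.0`). Scoring the predictions against
an adjudication table:

```bash
$ isolex evaluate --predictions mentions.csv --adjudications adjudications.csv
```

prints the confusion counts, exact and rounded precision/recall/F, and the
percent agreement. Review sizing:

```bash
$ isolex samplesize --population 1057 --prevalence 0.05
69
```

The same functionality is available as a library
(`isolex.run`, `isolex.metrics`, `isolex.review_sample_size`,
`isolex.generate`, …).

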