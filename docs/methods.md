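# Methods

This note documents the model behind `litcooc`, its tunable
parameters, the synthetic-data generator, and the numerical and design
choices that were genuinely open.

## Co-occurrence model

The unit of evidence is the sentence. A pair of distinct bioentities
(gene/protein names recognized by dictionary) receives one
co-occurrence instance per sentence in which both appear, typed by the
position of biointeraction trigger terms:

* **type 1** — some trigger mention lies strictly between the end of
  one member's mention and the start of the other's, for *any* choice
  of one mention of each member (any witnessing combination suffices);
* **type 2** — the sentence contains a trigger, but never between the
  names;
* **type 3** — the sentence contains no trigger;
* **type 4** — the pair shares an abstract but never a sentence.

"Strictly between" is evaluated on 0-based half-open character spans:
trigger span `[s, e)` is between mentions `A` and `B` (with `A` left of
`B`) iff `s >= A.end` and `e <= B.start`. A sentence instance carries
exactly one type — the best applicable (1 beats 2 beats 3) — because
the types grade confidence and a sentence has one best reading.

**Complexity exclusion.** Sentences with ≥ 4 *distinct entity keys* are
excluded from sentence-level extraction. Distinct keys, not mentions:
repeated mention of one protein adds no relational complexity. Pairs
whose only shared sentences were excluded remain eligible for type 4 —
exclusion removes sentence evidence, not the abstract-level
co-occurrence.

**Type-4 de-duplication.** A pair with any sentence-level instance in
an abstract gets no additional type-4 record there; this avoids
duplicate evidence rows while the cumulative threshold sets (≤1 ⊆ ≤2 ⊆
≤3 ⊆ ≤4) behave as expected. This was an open design point; the
no-duplication reading was chosen and is asserted by tests.

**Negation.** Deliberately not handled; a planted "does not bind"
sentence classifies as type 1 and a regression test keeps that
behaviour intentional. Negated biological facts are rare in abstracts
and detecting the scope of a negation reliably would cost more than
the few false positives it admits.

**Pair identity** uses normalized surface keys (case-fold + whitespace
collapse), not gene ids. Ambiguous surfaces (one name, several genes)
therefore aggregate as one node/pair; the gene-id mapping happens at
network build, where ambiguity is flagged rather than resolved.

## Tagging

Dictionary matching replaces statistical named-entity recognition
behind a pluggable contract: any tagger emitting non-overlapping
entity mentions whose spans slice the sentence text exactly can be
substituted without downstream change. Matching is case-insensitive,
token-bounded (a match may not begin or end inside an alphanumeric
run) and leftmost-longest, implemented as a longest-first regex
alternation with boundary lookarounds — deterministic and
order-independent. Entity mentions win conflicts with trigger
mentions; concept mentions may overlap entities (a word can name both
a protein and a process). Concept phrases tolerate a trailing "s"/"es"
on their final token ("brain" matches "brains"); full stemming was
rejected to keep matches auditable.

Sentence segmentation is rule-based: split after `.`/`!`/`?` followed
by whitespace and an uppercase letter or digit, guarded by a shipped,
user-extensible abbreviation list ("e.g.", "et al.", "Fig.", ...).
Offsets are 0-based half-open into the abstract body; the title is
prepended as leading context so title-only entities are taggable.
Every non-whitespace character falls in exactly one sentence span, so
evidence sentences can always be reconstructed.

## Parameters

| parameter | default | meaning |
|-----------|---------|---------|
| `min_length` (gene lexicon) | 2 chars | synonyms shorter than this are dropped (single-letter synonyms create pathological matches); official symbols are always indexed so every symbol stays retrievable |
| trigger dictionary | ~30 verb lemmas × base/-s/-ed (+ nominal) | editable configuration; the shipped default covers common interaction verbs (activate, induce, inhibit, bind, interact, phosphorylate, ...) |
| complexity threshold | 4 distinct entities | sentences at or above it yield no sentence-level pairs |
| concept suffixes | `s`, `es` | inflectional tolerance on the final phrase token |
| `max_type` (network) | 4 | edge filter; 1 = strictest |

## Evaluation protocol

Scoring is per (PMID, pair) instance on normalized keys — no fuzzy
matching, so synonym mismatches stay visible as a stratification
category instead of being silently repaired. The truth set is pooled:
curated gold interactions, minus those undetectable by definition
(self-interactions; partners that are not gene/protein symbols),
unioned with manually confirmed novel predictions supplied as input
(curation is ingested, never automated). Predictions are cumulative by
type threshold; recall = 100·TP/|truth|, precision = 100·TP/(TP+FP),
reported rounded to integers with unrounded values retained. Precision
with zero predictions is *missing*, never 0 or 100. Stratified recall
restricts the denominator to truths with the stratum flag true;
records with unknown flags are excluded from restricted strata and
counted.

## Synthetic fixtures

The generator emits a MEDLINE-format corpus plus the gene lexicon,
trigger list, concept list and gold TSV, from one seeded
configuration. Templates force each planted pair to exactly one type
(`"A binds B."`; trigger-after-both for type 2; trigger-free
co-sentential for type 3; different sentences for type 4); complex
sentences plant four names plus a trigger; negation sentences plant
"does not *verb*". Invented names are alphanumeric tokens absent from
English. Gold flags are truthful by construction, so stratified recall
over a fixture is computable by hand from the configuration.

The `two_hub_config` preset emulates a thematic neuro-disease corpus:
49 abstracts, two type-1 hubs of degree 48 and 11, one further type-1
pair, one type-2 hub–hub link, and the concept "aggregation" touching
both hub neighbourhoods.

What the generator does *not* emulate: paraphrase variety, synonym
usage drift, tokenization noise, genuinely ambiguous names in context,
and statistical tagger errors. Passing the closed-loop tests therefore
demonstrates the correctness of the classification machinery on
structurally faithful input, not the recall of dictionary tagging on
real prose — on real corpora, recall is dominated by dictionary
coverage, which is exactly what the stratified evaluation surfaces.

## Problem sizes

Tests and the acceptance script run on corpora of 4–49 abstracts, 100
randomized corpora for the monotonicity property, and 5 × 9 planted
pairs for closed-loop recovery; these sizes exercise every code path
while keeping the whole suite under a few seconds.

## Known limitations

* Dictionary-only entity recognition: no abbreviation expansion,
  species inference or coreference; recall on real text is bounded by
  lexicon coverage.
* Co-occurrence carries no directionality or verb semantics
  (activation vs inhibition are not distinguished).
* Network node `raw_terms` records the normalized key, not every
  original casing variant observed in text.
* The MEDLINE/PubMed readers are file-based only; no live E-utilities
  fetching in the core, which keeps analyses hermetic and repeatable.
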