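# litcooc

Concept-aware gene/protein co-occurrence mining from PubMed abstract
corpora.

Biologists exploring a research theme — say, protein aggregation in
neurodegenerative disease — often want the protein–protein interactions
(PPIs) discussed in a *selected* set of abstracts, filtered by the
biological concepts that matter to them, rather than a whole-database
interaction resource. `litcooc` is a library and command-line tool for
that workflow: it reads an abstract corpus, tags gene/protein names,
biointeraction trigger words and user concepts by dictionary matching,
classifies every bioentity pair co-occurrence into four confidence
types, builds filterable interaction networks, and benchmarks
predictions against gold-standard pair sets.

## The method

For each sentence *s* of an abstract, with tagged bioentity mentions and
biointeraction trigger mentions (e.g. *activates*, *induces*,
*inhibits*), every unordered pair of distinct bioentities is assigned a
co-occurrence type, from most to least significant:

| type | definition |
|------|------------|
| 1 | pair co-sentential with a trigger **between** the two names |
| 2 | pair co-sentential with a trigger **anywhere** in the sentence |
| 3 | pair co-sentential, no trigger in the sentence |
| 4 | pair co-occurs only at abstract level, never in one sentence |

Two rules complete the classifier. **Complexity exclusion:** sentences
containing four or more distinct bioentities are excluded from
sentence-level pair extraction (they are too complex to read
automatically; their entities remain eligible for type 4). **No
negation handling:** "A does not bind B" classifies exactly like
"A binds B" — negated facts are rare in abstracts and this keeps the
rule auditable; the behaviour is asserted by a regression test so it is
intentional, not accidental.

User *concepts* (free phrases such as "aggregation" or "colorectal
cancer") are matched in the text and attached to co-occurrences:
sentence-scoped for types 1–3, abstract-scoped for type 4. Networks
built from the aggregated pairs can be thresholded by type, merged with
concept nodes, restricted to the sub-network annotated with one
concept, and exported as GraphML, SIF or a TSV edge list.

For evaluation, predictions are scored per (PMID, pair) instance
against a pooled truth — curated gold interactions (self-interactions
and non-gene partners removed) unioned with manually confirmed novel
predictions — cumulatively per type threshold, with recall optionally
stratified by name detectability (term in dictionary, term detected,
sentence not complex).

## Worked example

Classify the pairs in one sentence about amyloid deposits:

```python
import litcooc as lc

text = ("Deposits of AMYLOID proteins, including Abeta and alpha-synuclein "
        "coexist in the brains of patients with dementia with Lewy bodies; "
        "however, it is not known how either of them interacts with tau to "
        "provoke neurofibrillary tangle formation across the tauopathies")
genes = lc.build_gene_lexicon([
    lc.GeneEntry("351", "APP", ("Abeta",)),
    lc.GeneEntry("6622", "SNCA", ("alpha-synuclein",)),
    lc.GeneEntry("4137", "MAPT", ("tau",)),
])
triggers = lc.build_interaction_lexicon(["interacts"])
tagged = lc.tag_abstract(lc.make_record("11786640", "", text), genes, triggers)
for cooc in lc.extract_sentence_pairs(tagged):
    print(cooc.pair, "type", cooc.cooc_type, "triggers:", cooc.interaction_terms)
```

prints

```
('abeta', 'alpha-synuclein') type 2 triggers: ('interacts',)
('abeta', 'tau') type 1 triggers: ('interacts',)
('alpha-synuclein', 'tau') type 1 triggers: ('interacts',)
```

Abeta and alpha-synuclein share the sentence and a trigger is present,
but *interacts* does not sit between their names — it refers to tau —
so the pair is type 2. Each pair involving tau has *interacts* between
the names, hence type 1.

## Command line

```
litcooc simulate --preset two-hub --seed 1 --out-dir fixtures/
litcooc extract  --corpus fixtures/corpus.medline.txt \
                 --gene-dict fixtures/gene_lexicon.tsv \
                 --concepts fixtures/concepts.txt --out-dir out/
litcooc network  --cooccurrences out/cooccurrences.tsv --max-type 1 \
                 --gene-dict fixtures/gene_lexicon.tsv --out net.graphml
litcooc eval     --predictions out/cooccurrences.tsv \
                 --gold fixtures/gold.tsv --out-dir report/
```

`simulate` writes a synthetic corpus with planted interactions (here: a
49-abstract corpus with two type-1 hubs of degree 48 and 11);
`extract` runs tagging and classification; `network` exports the
thresholded graph; `eval` writes recall/precision tables. Exit
statuses: 0 success, 2 usage error, 3 malformed data.

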