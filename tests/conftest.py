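import pytest

from litcooc import (
    GeneEntry,
    build_concept_lexicon,
    build_gene_lexicon,
    build_interaction_lexicon,
    make_record,
    tag_abstract,
)

DEPOSITS_SENTENCE = (
    "Deposits of AMYLOID proteins, including Abeta and alpha-synuclein coexist "
    "in the brains of patients with dementia with Lewy bodies; however, it is not "
    "known how either of them interacts with tau to provoke neurofibrillary tangle "
    "formation across the tauopathies"
)

NEUROSERPIN_SENTENCE = (
    "Neuroserpin binds Abeta and is a neuroprotective component of amyloid "
    "plaques in Alzheimer disease."
)


def record_for(text, pmid="1", title=""):
    return make_record(pmid, title, text)


def gene_lexicon_for(*names):
    return build_gene_lexicon(
        [GeneEntry(gene_id=str(100 + i), symbol=n) for i, n in enumerate(names)]
    )


def tagged_for(text, entity_names, interaction_terms=(), concepts=(), pmid="1"):
    """Tag a single-abstract corpus built from one text."""
    return tag_abstract(
        record_for(text, pmid=pmid),
        gene_lexicon_for(*entity_names),
        build_interaction_lexicon(interaction_terms),
        build_concept_lexicon(concepts),
    )


@pytest.fixture
def deposits_tagged():
    return tagged_for(
        DEPOSITS_SENTENCE,
        ["Abeta", "alpha-synuclein", "tau"],
        ["interacts"],
        ["brain", "aggregation"],
    )


def brute_force_type(entities, interactions, pair):
    """Independent classifier: enumerate every (mention-of-a,
    mention-of-b, interaction-mention) triple and test betweenness by
    exhaustive character-position comparison."""
    a_set = [m for m in entities if m.key == pair[0]]
    b_set = [m for m in entities if m.key == pair[1]]
    assert a_set and b_set
    for ma in a_set:
        for mb in b_set:
            inner_lo = min(ma.end, mb.end)
            inner_hi = max(ma.start, mb.start)
            for it in interactions:
                positions = range(it.start, it.end)
                if positions and all(inner_lo <= p < inner_hi for p in positions):
                    return 1
    return 2 if interactions else 3
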