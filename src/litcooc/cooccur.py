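"""Co-occurrence extraction and four-type classification — the core of
the method.

Every unordered pair of distinct bioentities found together in text is
classified into one of four confidence types, from most to least
significant:

* type 1 — the pair co-occurs in a sentence with a biointeraction term
  strictly between the two names;
* type 2 — the pair co-occurs in a sentence that contains a
  biointeraction term anywhere;
* type 3 — the pair co-occurs in a sentence without any biointeraction
  term;
* type 4 — the pair co-occurs only at the abstract level, never within
  one sentence.

Sentences containing four or more distinct bioentities are excluded
from sentence-level pair extraction: such sentences tend to be too
complex for reliable automatic reading. "Four or more" counts distinct
entity keys, not mentions — repeated mention of one protein adds no
relational complexity.

Negation is deliberately not handled: "A does not bind B" classifies
exactly like "A binds B". Sentences negating a biological fact are rare
in abstracts, and treating them like any other sentence trades a small
number of false positives for a much simpler, auditable rule.

Pair identity uses normalized surface keys (case-folded, whitespace
collapsed), not gene ids; mapping to gene symbols happens at network
build time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence, Union

from .tagger import ConceptMention, EntityMention, InteractionMention, TaggedAbstract

PathLike = Union[str, Path]

#: Sentences with this many or more distinct bioentities are excluded.
COMPLEXITY_THRESHOLD = 4

Pair = tuple[str, str]


def make_pair(a: str, b: str) -> Pair:
    """Canonical unordered pair: lexicographic member order."""
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class CoOccurrence:
    """One classified pair instance.

    ``scope`` is the sentence index for types 1–3 and ``None`` for the
    abstract-level type 4. ``interaction_terms`` is non-empty exactly
    for types 1–2: for type 1 the witnessing between-the-names terms,
    for type 2 all interaction surfaces in the sentence. ``evidence`` is
    the sentence text for types 1–3 and empty for type 4.
    """

    pmid: str
    pair: Pair
    cooc_type: int
    scope: int | None
    interaction_terms: tuple[str, ...] = ()
    concepts: tuple[str, ...] = ()
    evidence: str = ""


@dataclass(frozen=True)
class PairSummary:
    """A pair aggregated across all its instances in a corpus."""

    pair: Pair
    best_type: int
    support: int
    pmids: tuple[str, ...]
    concepts: tuple[str, ...]
    interaction_terms: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# Sentence-level classification
# ---------------------------------------------------------------------------

def _classify(
    entities: Sequence[EntityMention],
    interactions: Sequence[InteractionMention],
    pair: Pair,
) -> tuple[int, tuple[str, ...]]:
    a_mentions = [m for m in entities if m.key == pair[0]]
    b_mentions = [m for m in entities if m.key == pair[1]]
    if not a_mentions or not b_mentions:
        raise ValueError(f"pair {pair} has no mention for both members in sentence")
    witnesses: list[str] = []
    for ma in a_mentions:
        for mb in b_mentions:
            left, right = (ma, mb) if ma.start <= mb.start else (mb, ma)
            for it in interactions:
                if it.start >= left.end and it.end <= right.start:
                    witnesses.append(it.surface)
    if witnesses:
        seen: dict[str, None] = dict.fromkeys(witnesses)
        return 1, tuple(seen)
    if interactions:
        return 2, tuple(dict.fromkeys(it.surface for it in interactions))
    return 3, ()


def classify_pair(
    entities: Sequence[EntityMention],
    interactions: Sequence[InteractionMention],
    pair: Pair,
) -> int:
    """Classify one pair within one (non-excluded) sentence.

    Type 1 if some interaction mention lies strictly between the end of
    one member's mention and the start of the other's, for any choice of
    one mention of each member; else type 2 if the sentence contains any
    interaction mention; else type 3. Symmetric in the pair order.
    """
    return _classify(entities, interactions, make_pair(*pair))[0]


def extract_sentence_pairs(tagged: TaggedAbstract) -> list[CoOccurrence]:
    """Emit one CoOccurrence per (pair, sentence), types 1–3.

    Sentences with >= COMPLEXITY_THRESHOLD distinct entity keys yield
    nothing; self-pairs (one key mentioned twice) are never emitted.
    """
    out: list[CoOccurrence] = []
    for sent in tagged.record.sentences:
        entities = [e for e in tagged.entities if e.sentence_index == sent.index]
        keys = sorted(set(e.key for e in entities))
        if len(keys) < 2 or len(keys) >= COMPLEXITY_THRESHOLD:
            continue
        interactions = [
            i for i in tagged.interactions if i.sentence_index == sent.index
        ]
        for a, b in combinations(keys, 2):
            cooc_type, terms = _classify(entities, interactions, (a, b))
            out.append(
                CoOccurrence(
                    pmid=tagged.pmid,
                    pair=(a, b),
                    cooc_type=cooc_type,
                    scope=sent.index,
                    interaction_terms=terms,
                    evidence=sent.text,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Abstract-level pairs (type 4)
# ---------------------------------------------------------------------------

def extract_abstract_pairs(
    tagged: TaggedAbstract, sentence_pairs: Sequence[CoOccurrence]
) -> list[CoOccurrence]:
    """Emit type-4 CoOccurrences for pairs that co-occur in the abstract
    but have no sentence-level instance there.

    Pairs whose only shared sentences were excluded by the complexity
    rule are eligible: exclusion removes sentence evidence, not the
    abstract-level co-occurrence.
    """
    keys = sorted(set(e.key for e in tagged.entities))
    covered = {c.pair for c in sentence_pairs}
    out: list[CoOccurrence] = []
    for a, b in combinations(keys, 2):
        if (a, b) in covered:
            continue
        out.append(
            CoOccurrence(pmid=tagged.pmid, pair=(a, b), cooc_type=4, scope=None)
        )
    return out


# ---------------------------------------------------------------------------
# Concepts
# ---------------------------------------------------------------------------

def associate_concepts(
    cooccurrences: Iterable[CoOccurrence],
    concept_mentions: Sequence[ConceptMention],
) -> list[CoOccurrence]:
    """Attach concept phrases: sentence-scoped for types 1–3,
    abstract-scoped for type 4."""
    all_concepts = tuple(dict.fromkeys(c.phrase for c in concept_mentions))
    by_sentence: dict[int, tuple[str, ...]] = {}
    for c in concept_mentions:
        cur = by_sentence.get(c.sentence_index, ())
        if c.phrase not in cur:
            by_sentence[c.sentence_index] = cur + (c.phrase,)
    out: list[CoOccurrence] = []
    for cooc in cooccurrences:
        if cooc.cooc_type <= 3:
            concepts = by_sentence.get(cooc.scope, ())
        else:
            concepts = all_concepts
        out.append(replace(cooc, concepts=concepts))
    return out


def extract_cooccurrences(tagged: TaggedAbstract) -> list[CoOccurrence]:
    """Full per-abstract pipeline: sentence pairs, then abstract-level
    type-4 pairs, then concept association."""
    sentence_pairs = extract_sentence_pairs(tagged)
    abstract_pairs = extract_abstract_pairs(tagged, sentence_pairs)
    return associate_concepts(sentence_pairs + abstract_pairs, tagged.concepts)


def extract_corpus(
    records,
    gene_lexicon,
    interaction_lexicon=None,
    concept_lexicon=None,
) -> tuple[list[TaggedAbstract], list[CoOccurrence]]:
    """Tag and extract a whole corpus: returns the tagged abstracts and
    all classified co-occurrence instances."""
    from .tagger import tag_abstract

    tagged = [
        tag_abstract(r, gene_lexicon, interaction_lexicon, concept_lexicon)
        for r in records
    ]
    coocs = [c for ta in tagged for c in extract_cooccurrences(ta)]
    return tagged, coocs


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def summarize_pairs(cooccurrences: Iterable[CoOccurrence]) -> list[PairSummary]:
    """Group instances by pair across abstracts; best_type is the
    minimum (most significant) type observed."""
    groups: dict[Pair, list[CoOccurrence]] = {}
    for cooc in cooccurrences:
        groups.setdefault(cooc.pair, []).append(cooc)
    out: list[PairSummary] = []
    for pair in sorted(groups):
        instances = groups[pair]
        out.append(
            PairSummary(
                pair=pair,
                best_type=min(c.cooc_type for c in instances),
                support=len(instances),
                pmids=tuple(sorted(set(c.pmid for c in instances))),
                concepts=tuple(sorted(set(p for c in instances for p in c.concepts))),
                interaction_terms=tuple(
                    sorted(set(t for c in instances for t in c.interaction_terms))
                ),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

COOC_COLUMNS = (
    "pmid", "term1", "term2", "type", "sentence_index",
    "interaction_terms", "concepts", "evidence",
)


def write_cooccurrence_table(
    cooccurrences: Iterable[CoOccurrence], path: PathLike
) -> None:
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(COOC_COLUMNS)
        for c in cooccurrences:
            writer.writerow(
                [
                    c.pmid, c.pair[0], c.pair[1], c.cooc_type,
                    "" if c.scope is None else c.scope,
                    "|".join(c.interaction_terms),
                    "|".join(c.concepts),
                    c.evidence,
                ]
            )


def read_cooccurrence_table(path: PathLike) -> list[CoOccurrence]:
    out: list[CoOccurrence] = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        missing = set(COOC_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise ValueError(f"co-occurrence table missing columns: {sorted(missing)}")
        for row in reader:
            out.append(
                CoOccurrence(
                    pmid=row["pmid"],
                    pair=make_pair(row["term1"], row["term2"]),
                    cooc_type=int(row["type"]),
                    scope=int(row["sentence_index"]) if row["sentence_index"] else None,
                    interaction_terms=tuple(
                        t for t in row["interaction_terms"].split("|") if t
                    ),
                    concepts=tuple(t for t in row["concepts"].split("|") if t),
                    evidence=row["evidence"],
                )
            )
    return out
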