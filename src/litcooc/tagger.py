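"""Dictionary tagging of entity, biointeraction and concept mentions.

Each sentence of an abstract is scanned for surface forms from the
three lexicons. Matching is case-insensitive, respects token boundaries
(a match may not begin or end inside an alphanumeric run) and resolves
overlapping dictionary hits by leftmost-longest preference. The entity
tagger is the anchor of the method and sits behind a deliberately thin
contract: any tagger producing non-overlapping ``EntityMention``s whose
spans slice the sentence text exactly can substitute for it without
downstream change.

Tagging is pure — no state is carried between abstracts.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from .corpus_io import AbstractRecord
from .lexicon import (
    ConceptLexicon,
    GeneLexicon,
    InteractionLexicon,
    normalize_term,
)

PathLike = Union[str, Path]

# Inflectional suffixes tolerated when matching concept phrases
# ("brain" matches "brains"); full stemming is deliberately avoided so
# every match stays auditable.
CONCEPT_SUFFIXES = ("es", "s")


@dataclass(frozen=True)
class EntityMention:
    """A tagged gene/protein surface form.

    Offsets are relative to the abstract body. ``gene_ids`` carries all
    candidate gene ids for the surface (ambiguity preserved);
    ``display_symbol`` is the official symbol of the first candidate,
    with the raw surface kept alongside in ``surface``.
    """

    surface: str
    sentence_index: int
    start: int
    end: int
    gene_ids: tuple[str, ...]
    display_symbol: str

    @property
    def key(self) -> str:
        return normalize_term(self.surface)


@dataclass(frozen=True)
class InteractionMention:
    surface: str
    sentence_index: int
    start: int
    end: int


@dataclass(frozen=True)
class ConceptMention:
    phrase: str
    sentence_index: int
    start: int
    end: int


@dataclass
class TaggedAbstract:
    record: AbstractRecord
    entities: list[EntityMention] = field(default_factory=list)
    interactions: list[InteractionMention] = field(default_factory=list)
    concepts: list[ConceptMention] = field(default_factory=list)

    @property
    def pmid(self) -> str:
        return self.record.pmid


# ---------------------------------------------------------------------------
# Pattern construction
# ---------------------------------------------------------------------------

def _phrase_pattern(surface: str, suffixes: Sequence[str] = ()) -> str:
    tokens = [re.escape(t) for t in surface.split()]
    if suffixes:
        tokens[-1] += "(?:" + "|".join(re.escape(s) for s in suffixes) + ")?"
    return r"\s+".join(tokens)


def _compile(surfaces: Iterable[str], suffixes: Sequence[str] = ()) -> re.Pattern | None:
    """Longest-first alternation with alphanumeric-boundary lookarounds.

    ``re`` picks the first alternative that matches at the leftmost
    position; sorting alternatives longest-first therefore yields the
    leftmost-longest match, and ``finditer`` makes matches
    non-overlapping.
    """
    forms = sorted(set(surfaces), key=lambda s: (-len(s), s))
    if not forms:
        return None
    body = "|".join(_phrase_pattern(s, suffixes) for s in forms)
    return re.compile(
        r"(?<![A-Za-z0-9])(?:" + body + r")(?![A-Za-z0-9])", re.IGNORECASE
    )


def _pattern_for(lexicon, surfaces, suffixes=()) -> re.Pattern | None:
    # Compiled patterns are cached on the lexicon object; lexicons are
    # treated as immutable after construction.
    cached = getattr(lexicon, "_litcooc_pattern", None)
    if cached is None:
        cached = _compile(surfaces, suffixes)
        setattr(lexicon, "_litcooc_pattern", cached)
    return cached


def _overlaps(start: int, end: int, mentions: Iterable) -> bool:
    return any(m.start < end and start < m.end for m in mentions)


# ---------------------------------------------------------------------------
# Taggers
# ---------------------------------------------------------------------------

def tag_entities(record: AbstractRecord, lexicon: GeneLexicon) -> list[EntityMention]:
    """Tag gene/protein mentions sentence by sentence.

    Every mention carries the full candidate gene-id set from the
    lexicon index. Mentions within one sentence never overlap
    (leftmost-longest resolution).
    """
    if not lexicon.index:
        raise ValueError("gene lexicon is empty")
    pattern = _pattern_for(lexicon, lexicon.surfaces())
    mentions: list[EntityMention] = []
    for sent in record.sentences:
        for m in pattern.finditer(sent.text):
            surface = m.group()
            gene_ids = lexicon.lookup(surface)
            if not gene_ids:
                continue
            mentions.append(
                EntityMention(
                    surface=surface,
                    sentence_index=sent.index,
                    start=sent.start + m.start(),
                    end=sent.start + m.end(),
                    gene_ids=gene_ids,
                    display_symbol=lexicon.symbol_for(gene_ids[0]),
                )
            )
    return mentions


def tag_interactions(
    record: AbstractRecord,
    lexicon: InteractionLexicon,
    entity_mentions: Sequence[EntityMention] = (),
) -> list[InteractionMention]:
    """Tag biointeraction trigger terms.

    Matches overlapping an entity mention are discarded: an entity
    surface cannot double as an interaction term (the entity reading
    wins).
    """
    pattern = _pattern_for(lexicon, lexicon.terms)
    if pattern is None:
        return []
    mentions: list[InteractionMention] = []
    for sent in record.sentences:
        in_sentence = [e for e in entity_mentions if e.sentence_index == sent.index]
        for m in pattern.finditer(sent.text):
            start, end = sent.start + m.start(), sent.start + m.end()
            if _overlaps(start, end, in_sentence):
                continue
            mentions.append(
                InteractionMention(
                    surface=m.group(), sentence_index=sent.index, start=start, end=end
                )
            )
    return mentions


def tag_concepts(record: AbstractRecord, lexicon: ConceptLexicon) -> list[ConceptMention]:
    """Tag user concept phrases, one mention per occurrence.

    Case-insensitive; the final token of a phrase may carry a short
    inflectional suffix ("s"/"es"). Overlap with entity mentions is
    allowed — a word can name both a protein and a process.
    """
    if not lexicon.phrases:
        return []
    pattern = _pattern_for(lexicon, lexicon.phrases, CONCEPT_SUFFIXES)
    by_form: dict[str, str] = {}
    for phrase in lexicon.phrases:
        by_form[phrase] = phrase
    mentions: list[ConceptMention] = []
    for sent in record.sentences:
        for m in pattern.finditer(sent.text):
            matched = normalize_term(m.group())
            phrase = by_form.get(matched)
            if phrase is None:
                # Strip the tolerated suffix to recover the lexicon phrase.
                for suf in CONCEPT_SUFFIXES:
                    if matched.endswith(suf) and matched[: -len(suf)] in by_form:
                        phrase = matched[: -len(suf)]
                        break
            if phrase is None:
                continue
            mentions.append(
                ConceptMention(
                    phrase=phrase,
                    sentence_index=sent.index,
                    start=sent.start + m.start(),
                    end=sent.start + m.end(),
                )
            )
    return mentions


def tag_abstract(
    record: AbstractRecord,
    gene_lexicon: GeneLexicon,
    interaction_lexicon: InteractionLexicon | None = None,
    concept_lexicon: ConceptLexicon | None = None,
) -> TaggedAbstract:
    """Apply the three taggers in order entities → interactions → concepts."""
    entities = tag_entities(record, gene_lexicon)
    interactions = (
        tag_interactions(record, interaction_lexicon, entities)
        if interaction_lexicon is not None and len(interaction_lexicon)
        else []
    )
    concepts = (
        tag_concepts(record, concept_lexicon)
        if concept_lexicon is not None and len(concept_lexicon)
        else []
    )
    return TaggedAbstract(
        record=record, entities=entities, interactions=interactions, concepts=concepts
    )


# ---------------------------------------------------------------------------
# Serialization (inspection / caching)
# ---------------------------------------------------------------------------

MENTION_COLUMNS = ("pmid", "kind", "sentence_index", "start", "end", "surface", "ids")


def write_mentions_tsv(tagged: Iterable[TaggedAbstract], path: PathLike) -> None:
    """Write all mentions of a tagged corpus as a TSV for inspection."""
    with open(path, "w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MENTION_COLUMNS)
        for ta in tagged:
            for e in ta.entities:
                writer.writerow(
                    [ta.pmid, "entity", e.sentence_index, e.start, e.end,
                     e.surface, "|".join(e.gene_ids)]
                )
            for i in ta.interactions:
                writer.writerow(
                    [ta.pmid, "interaction", i.sentence_index, i.start, i.end, i.surface, ""]
                )
            for c in ta.concepts:
                writer.writerow(
                    [ta.pmid, "concept", c.sentence_index, c.start, c.end, c.phrase, ""]
                )
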