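"""Deterministic synthetic corpora with planted interaction structure.

The generator emits everything the pipeline reads — a MEDLINE-format
corpus, a gene lexicon TSV, a biointeraction-term file, a concept list
and a gold-standard TSV — from a single seeded configuration, so every
stage is testable end to end without downloads.

Planted pairs are templated to force exactly one co-occurrence type:

* type 1: ``"A binds B."`` — trigger between the names;
* type 2: ``"A and B colocalize where it interacts with membranes."``
  — trigger in the sentence but after both names;
* type 3: ``"A and B coexist."`` — no trigger at all;
* type 4: the two names in different sentences of one abstract.

Complex sentences (four planted names plus a trigger) exercise the
exclusion rule; ``"does not bind"`` sentences exercise the method's
deliberate negation blindness. The gold file's detectability flags are
truthful by construction, so stratified recall over a fixture is
computable by hand from the configuration.

Invented entity names are alphanumeric tokens absent from English text,
avoiding accidental dictionary matches. The templates aim at structural
coverage of the classifier, not linguistic realism.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

from .corpus_io import AbstractRecord, CorpusLoad, make_record
from .evalbench import GoldInteraction
from .lexicon import (
    ConceptLexicon,
    GeneEntry,
    GeneLexicon,
    InteractionLexicon,
    build_concept_lexicon,
    build_gene_lexicon,
    build_interaction_lexicon,
    normalize_term,
)

PathLike = Union[str, Path]

FIRST_PMID = 9000001

_DISTRACTORS = (
    "The cohort was followed for several years.",
    "Samples were processed under standard laboratory conditions.",
    "Results were consistent across replicates.",
    "The study design was approved by the local committee.",
    "Further work will be needed to confirm these observations.",
    "Measurements were taken at regular intervals.",
)


class FixtureConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PlantedPair:
    pair: tuple[str, str]
    target_type: int
    concepts: tuple[str, ...] = ()
    verb: Optional[str] = None  # 3rd-person form; defaults to config's first verb


@dataclass(frozen=True)
class PlantedTruth:
    """What was planted where — the oracle the closed-loop tests check
    extraction against."""

    pmid: str
    pair: tuple[str, str]  # normalized keys, canonical order
    target_type: Optional[int]  # None: no sentence/abstract-level plant expected
    concepts: tuple[str, ...] = ()
    complex_sentence: bool = False
    negated: bool = False
    detectable: bool = True


@dataclass
class FixtureConfig:
    seed: int = 0
    n_abstracts: int = 10
    planted_pairs: tuple[PlantedPair, ...] = ()
    entity_pool: tuple[tuple[str, str], ...] = ()  # (name, gene_id); auto-extended
    distractor_sentences_per_abstract: int = 1
    complex_sentence_count: int = 0
    negation_count: int = 0
    undetectable_gold_count: int = 0
    interaction_verbs: tuple[str, ...] = ("binds", "activates", "inhibits", "interacts")

    def validate(self) -> None:
        if self.seed < 0:
            raise FixtureConfigError("seed must be non-negative")
        needs_verb = any(p.target_type in (1, 2) for p in self.planted_pairs)
        if (needs_verb or self.negation_count or self.complex_sentence_count) \
                and not self.interaction_verbs:
            raise FixtureConfigError(
                "type-1/2 plants, negations and complex sentences require "
                "a non-empty verb pool"
            )
        if self.planted_pairs and self.n_abstracts < 1:
            raise FixtureConfigError("planted pairs require n_abstracts >= 1")
        for p in self.planted_pairs:
            if p.target_type not in (1, 2, 3, 4):
                raise FixtureConfigError(f"bad target_type {p.target_type}")
            if normalize_term(p.pair[0]) == normalize_term(p.pair[1]):
                raise FixtureConfigError(f"self-pair plant {p.pair}")
            if p.verb is not None and p.verb not in self.interaction_verbs:
                raise FixtureConfigError(f"verb {p.verb!r} not in verb pool")


@dataclass
class FixtureBundle:
    """In-memory fixture plus renderers for the on-disk formats."""

    config: FixtureConfig
    records: list[AbstractRecord]
    gene_lexicon: GeneLexicon
    interaction_lexicon: InteractionLexicon
    concept_lexicon: ConceptLexicon
    gold: list[GoldInteraction]
    planted: list[PlantedTruth]
    gene_entries: list[GeneEntry] = field(default_factory=list)

    @property
    def corpus(self) -> CorpusLoad:
        return CorpusLoad(records=self.records, skipped=0)


def _base_form(verb: str) -> str:
    return verb[:-1] if verb.endswith("s") else verb


def plant_sentence(
    pair: Sequence[str],
    target_type: int,
    verb: Optional[str] = None,
    concept: Optional[str] = None,
) -> str:
    """Render one sentence that classifies to exactly ``target_type``
    (1-3) and mentions ``concept`` iff requested."""
    a, b = pair
    tail = f" during {concept}" if concept else ""
    if target_type == 1:
        if not verb:
            raise FixtureConfigError("type-1 plant requires a verb")
        return f"{a} {verb} {b}{tail}."
    if target_type == 2:
        if not verb:
            raise FixtureConfigError("type-2 plant requires a verb")
        # Trigger after both names, never between them; the filler noun
        # is not a bioentity so the sentence stays below the complexity cap.
        return f"{a} and {b} colocalize{tail} where it {verb} with membranes."
    if target_type == 3:
        return f"{a} and {b} coexist{tail}."
    raise FixtureConfigError(f"plant_sentence handles types 1-3, got {target_type}")


def _gold_row(
    pmid: str,
    pair: tuple[str, str],
    detectable: bool = True,
    complex_sentence: bool = False,
) -> GoldInteraction:
    a, b = sorted(normalize_term(x) for x in pair)
    return GoldInteraction(
        pmid=pmid,
        pair=(a, b),
        is_self=False,
        non_gene_symbol=False,
        both_in_dictionary=detectable,
        both_detected=detectable,
        complex_sentence=complex_sentence,
    )


def generate_bundle(config: FixtureConfig) -> FixtureBundle:
    """Build the fixture in memory. Reproducible: a fixed seed yields
    identical output."""
    config.validate()
    rng = random.Random(config.seed)
    verbs = config.interaction_verbs
    default_verb = verbs[0] if verbs else None

    abstracts: list[list[str]] = [[] for _ in range(config.n_abstracts)]
    pmid_of = lambda i: str(FIRST_PMID + i)
    planted: list[PlantedTruth] = []
    gold: list[GoldInteraction] = []
    names: dict[str, None] = {}  # ordered set of detectable entity names

    for name, _gid in config.entity_pool:
        names.setdefault(name)

    # Planted pairs, round-robin over the regular abstracts.
    for i, plant in enumerate(config.planted_pairs):
        idx = i % config.n_abstracts
        a, b = plant.pair
        names.setdefault(a)
        names.setdefault(b)
        verb = plant.verb or default_verb
        concept = plant.concepts[0] if plant.concepts else None
        if plant.target_type <= 3:
            abstracts[idx].append(
                plant_sentence((a, b), plant.target_type, verb, concept)
            )
            for extra in plant.concepts[1:]:
                abstracts[idx].append(f"This study concerns {extra}.")
        else:
            abstracts[idx].append(f"{a} was examined in this model.")
            abstracts[idx].append(f"{b} was examined in this model.")
            for extra in plant.concepts:
                abstracts[idx].append(f"This study concerns {extra}.")
        key = tuple(sorted(normalize_term(x) for x in (a, b)))
        pmid = pmid_of(idx)
        planted.append(
            PlantedTruth(
                pmid=pmid, pair=key, target_type=plant.target_type,
                concepts=tuple(normalize_term(c) for c in plant.concepts),
            )
        )
        gold.append(_gold_row(pmid, (a, b)))

    # Negation sentences: the classifier is negation-blind by design, so
    # these plant as type 1.
    next_idx = config.n_abstracts
    extra_abstracts: list[tuple[str, list[str]]] = []
    for i in range(config.negation_count):
        a, b = f"NGA{i + 1}X", f"NGB{i + 1}X"
        names.setdefault(a)
        names.setdefault(b)
        base = _base_form(default_verb)
        pmid = pmid_of(next_idx)
        extra_abstracts.append((pmid, [f"{a} does not {base} {b}."]))
        next_idx += 1
        planted.append(
            PlantedTruth(
                pmid=pmid,
                pair=tuple(sorted(normalize_term(x) for x in (a, b))),
                target_type=1, negated=True,
            )
        )
        gold.append(_gold_row(pmid, (a, b)))

    # Complex sentences: four distinct bioentities plus a trigger — the
    # exclusion rule must suppress all sentence-level pairs here.
    for i in range(config.complex_sentence_count):
        group = [f"CX{i + 1}{c}Z" for c in "ABCD"]
        for n in group:
            names.setdefault(n)
        base = _base_form(default_verb)
        pmid = pmid_of(next_idx)
        extra_abstracts.append(
            (pmid, [f"{group[0]}, {group[1]}, {group[2]} and {group[3]} {base} strongly."])
        )
        next_idx += 1
        key = tuple(sorted(normalize_term(x) for x in group[:2]))
        planted.append(
            PlantedTruth(pmid=pmid, pair=key, target_type=None, complex_sentence=True)
        )
        gold.append(_gold_row(pmid, (group[0], group[1]), complex_sentence=True))

    # Gold pairs whose names are absent from the gene lexicon: present
    # in text, undetectable by the dictionary tagger.
    undetectable_names: list[str] = []
    for i in range(config.undetectable_gold_count):
        a, b = f"UDA{i + 1}Q", f"UDB{i + 1}Q"
        undetectable_names.extend([a, b])
        pmid = pmid_of(next_idx)
        verb = default_verb or "binds"
        extra_abstracts.append((pmid, [f"{a} {verb} {b}."]))
        next_idx += 1
        key = tuple(sorted(normalize_term(x) for x in (a, b)))
        planted.append(
            PlantedTruth(pmid=pmid, pair=key, target_type=None, detectable=False)
        )
        gold.append(_gold_row(pmid, (a, b), detectable=False))

    # Distractor filler, deterministic via the seeded generator.
    for sentences in abstracts:
        for _ in range(config.distractor_sentences_per_abstract):
            sentences.append(rng.choice(_DISTRACTORS))

    records: list[AbstractRecord] = []
    for i, sentences in enumerate(abstracts):
        if not sentences:
            continue
        pmid = pmid_of(i)
        records.append(
            make_record(pmid, f"Synthetic record {pmid}.", " ".join(sentences))
        )
    for pmid, sentences in extra_abstracts:
        records.append(
            make_record(pmid, f"Synthetic record {pmid}.", " ".join(sentences))
        )
    records.sort(key=lambda r: r.pmid)

    entries = [
        GeneEntry(gene_id=str(9000 + i), symbol=name, synonyms=())
        for i, name in enumerate(names, start=1)
    ]
    gene_lexicon = build_gene_lexicon(entries) if entries else GeneLexicon(entries=[])
    term_list: list[str] = []
    for verb in verbs:
        term_list.extend([verb, _base_form(verb)])
    interaction_lexicon = build_interaction_lexicon(term_list)
    concept_lexicon = build_concept_lexicon(
        c for p in config.planted_pairs for c in p.concepts
    )
    return FixtureBundle(
        config=config,
        records=records,
        gene_lexicon=gene_lexicon,
        interaction_lexicon=interaction_lexicon,
        concept_lexicon=concept_lexicon,
        gold=gold,
        planted=planted,
        gene_entries=entries,
    )


# ---------------------------------------------------------------------------
# File rendering
# ---------------------------------------------------------------------------

def render_medline(records: Sequence[AbstractRecord]) -> str:
    chunks = []
    for r in records:
        title = r.title or "Untitled."
        abstract = r.body[len(r.title):].strip() if r.title else r.body
        chunks.append(f"PMID- {r.pmid}\nTI  - {title}\nAB  - {abstract}\n")
    return "\n".join(chunks)


def render_gene_lexicon(entries: Sequence[GeneEntry]) -> str:
    return "".join(
        f"{e.gene_id}\t{e.symbol}\t{'|'.join(e.synonyms)}\n" for e in entries
    )


def render_gold(gold: Sequence[GoldInteraction]) -> str:
    def flag(v: Optional[bool]) -> str:
        return "" if v is None else ("1" if v else "0")

    lines = [
        "pmid\tterm1\tterm2\tis_self\tnon_gene_symbol\tboth_in_dictionary"
        "\tboth_detected\tcomplex_sentence"
    ]
    for g in gold:
        lines.append(
            "\t".join(
                [
                    g.pmid, g.pair[0], g.pair[1],
                    flag(g.is_self), flag(g.non_gene_symbol),
                    flag(g.both_in_dictionary), flag(g.both_detected),
                    flag(g.complex_sentence),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def write_bundle(bundle: FixtureBundle, outdir: PathLike) -> dict[str, Path]:
    """Write the fixture bundle in the formats the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "corpus": outdir / "corpus.medline.txt",
        "gene_lexicon": outdir / "gene_lexicon.tsv",
        "interaction_terms": outdir / "interaction_terms.txt",
        "concepts": outdir / "concepts.txt",
        "gold": outdir / "gold.tsv",
    }
    paths["corpus"].write_text(render_medline(bundle.records), "utf-8")
    paths["gene_lexicon"].write_text(render_gene_lexicon(bundle.gene_entries), "utf-8")
    paths["interaction_terms"].write_text(
        "".join(t + "\n" for t in sorted(bundle.interaction_lexicon.terms)), "utf-8"
    )
    paths["concepts"].write_text(
        "".join(p + "\n" for p in bundle.concept_lexicon.phrases), "utf-8"
    )
    paths["gold"].write_text(render_gold(bundle.gold), "utf-8")
    return paths


def generate_corpus(config: FixtureConfig, outdir: PathLike) -> dict[str, Path]:
    """Generate a fixture and write it to ``outdir``; returns the file
    paths keyed by role."""
    return write_bundle(generate_bundle(config), outdir)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def two_hub_config(seed: int = 0) -> FixtureConfig:
    """A 49-abstract corpus with two type-1 hubs of degree 48 and 11,
    one further type-1 pair between two other proteins, and one type-2
    link between the hubs, with the concept "aggregation" touching both
    hub neighbourhoods. The planted degrees are recoverable exactly by
    the pipeline at threshold 1."""
    plants: list[PlantedPair] = []
    for i in range(48):
        concepts = ("aggregation",) if i == 0 else ()
        plants.append(PlantedPair(("HUBA", f"HAP{i + 1:02d}"), 1, concepts, "binds"))
    for i in range(11):
        concepts = ("aggregation",) if i == 0 else ()
        plants.append(PlantedPair(("HUBB", f"HBP{i + 1:02d}"), 1, concepts, "inhibits"))
    plants.append(PlantedPair(("EXTC", "EXTD"), 1, (), "activates"))
    plants.append(PlantedPair(("HUBA", "HUBB"), 2, (), "interacts"))
    return FixtureConfig(
        seed=seed,
        n_abstracts=49,
        planted_pairs=tuple(plants),
        distractor_sentences_per_abstract=1,
    )


def random_config(seed: int, n_pairs: int = 6, n_abstracts: int = 4) -> FixtureConfig:
    """A small randomized configuration: ``n_pairs`` plants with random
    target types, verbs and optional concepts. Used for property-style
    checks across many corpora."""
    rng = random.Random(seed)
    verbs = ("binds", "activates", "inhibits", "interacts")
    concepts = ("aggregation", "phosphorylation", "apoptosis")
    plants = []
    for i in range(n_pairs):
        pair = (f"RP{seed % 1000}A{i}", f"RP{seed % 1000}B{i}")
        target = rng.choice((1, 2, 3, 4))
        cs = (rng.choice(concepts),) if rng.random() < 0.5 else ()
        plants.append(PlantedPair(pair, target, cs, rng.choice(verbs)))
    return FixtureConfig(
        seed=seed,
        n_abstracts=n_abstracts,
        planted_pairs=tuple(plants),
        distractor_sentences_per_abstract=rng.randint(0, 2),
        complex_sentence_count=rng.randint(0, 1),
        negation_count=rng.randint(0, 1),
        interaction_verbs=verbs,
    )
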