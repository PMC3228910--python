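"""The three dictionaries of the method.

* a gene/protein name lexicon (TSV: gene id, official symbol,
  pipe-separated synonyms), indexed case-insensitively with ambiguity
  preserved — a surface form may resolve to several gene ids;
* a biointeraction-term dictionary (one term per line; an editable
  default of common interaction verbs ships with the package);
* an optional list of user concepts (free phrases of one or more words).

Matching throughout the pipeline is case-insensitive; normalization of a
surface form is case-folding plus whitespace collapse.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Union

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

DEFAULT_MIN_SURFACE_LENGTH = 2


class LexiconFormatError(ValueError):
    """Raised for malformed lexicon files (the message names the line)."""


def normalize_term(surface: str) -> str:
    """Canonical form used for index keys and pair identity:
    case-fold and collapse internal whitespace."""
    return re.sub(r"\s+", " ", surface.strip()).casefold()


def _read_lines(source: Union[PathLike, IO[str]]) -> list[str]:
    if hasattr(source, "read"):
        return source.read().splitlines()
    return Path(source).read_text("utf-8").splitlines()


# ---------------------------------------------------------------------------
# Gene/protein lexicon
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneEntry:
    gene_id: str
    symbol: str
    synonyms: tuple[str, ...] = ()


@dataclass
class GeneLexicon:
    """Name dictionary with a case-folded surface-form index.

    ``index`` maps a normalized surface form to the ordered tuple of
    gene ids it may refer to. Ambiguity is preserved, never resolved:
    a form shared by two genes maps to both ids.
    """

    entries: list[GeneEntry]
    index: dict[str, tuple[str, ...]] = field(default_factory=dict)
    symbols: dict[str, str] = field(default_factory=dict)  # gene_id -> symbol
    dropped_short: int = 0
    min_length: int = DEFAULT_MIN_SURFACE_LENGTH

    def lookup(self, surface: str) -> tuple[str, ...]:
        """Total lookup: any query returns a (possibly empty) gene-id tuple."""
        return self.index.get(normalize_term(surface), ())

    def surfaces(self) -> list[str]:
        return list(self.index)

    def symbol_for(self, gene_id: str) -> str:
        return self.symbols.get(gene_id, gene_id)


def build_gene_lexicon(
    entries: Iterable[GeneEntry],
    min_length: int = DEFAULT_MIN_SURFACE_LENGTH,
) -> GeneLexicon:
    lex = GeneLexicon(entries=list(entries), min_length=min_length)
    if not lex.entries:
        raise LexiconFormatError("gene lexicon is empty (it is mandatory)")
    for entry in lex.entries:
        lex.symbols[entry.gene_id] = entry.symbol
        # Official symbols are always indexed; the minimum-length guard
        # applies to synonyms only (single-letter synonyms create
        # pathological false matches).
        for surface, is_symbol in [(entry.symbol, True)] + [
            (s, False) for s in entry.synonyms
        ]:
            key = normalize_term(surface)
            if not key:
                continue
            if not is_symbol and len(key) < min_length:
                lex.dropped_short += 1
                continue
            ids = lex.index.get(key, ())
            if entry.gene_id not in ids:
                lex.index[key] = ids + (entry.gene_id,)
    return lex


def load_gene_dictionary(
    path: PathLike, min_length: int = DEFAULT_MIN_SURFACE_LENGTH
) -> GeneLexicon:
    """Load the gene/protein name TSV: gene_id, official_symbol,
    pipe-separated synonyms (third column may be empty)."""
    entries: list[GeneEntry] = []
    with open(path, encoding="utf-8", newline="") as handle:
        for lineno, row in enumerate(csv.reader(handle, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2 or not row[0].strip() or not row[1].strip():
                raise LexiconFormatError(
                    f"line {lineno}: expected columns gene_id, official_symbol"
                    f"[, synonyms], got {row!r}"
                )
            synonyms = tuple(
                s.strip() for s in (row[2] if len(row) > 2 else "").split("|") if s.strip()
            )
            entries.append(GeneEntry(row[0].strip(), row[1].strip(), synonyms))
    if not entries:
        raise LexiconFormatError(f"gene lexicon {path} has no entries")
    lex = build_gene_lexicon(entries, min_length=min_length)
    if lex.dropped_short:
        logger.info(
            "dropped %d surface forms shorter than %d characters",
            lex.dropped_short, min_length,
        )
    return lex


# ---------------------------------------------------------------------------
# Biointeraction terms
# ---------------------------------------------------------------------------

@dataclass
class InteractionLexicon:
    """Set of normalized biointeraction trigger terms ("binds",
    "inhibits", ...). Must be non-empty when classification of types 1-2
    is requested."""

    terms: frozenset[str]

    def __contains__(self, surface: str) -> bool:
        return normalize_term(surface) in self.terms

    def __len__(self) -> int:
        return len(self.terms)


def build_interaction_lexicon(terms: Iterable[str]) -> InteractionLexicon:
    return InteractionLexicon(
        terms=frozenset(t for t in (normalize_term(x) for x in terms) if t)
    )


def load_interaction_terms(source: Union[PathLike, IO[str]]) -> InteractionLexicon:
    """Load a biointeraction-term file: one term per line, '#' comments
    allowed; case-folded and deduplicated."""
    terms = [
        line.strip() for line in _read_lines(source)
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return build_interaction_lexicon(terms)


def default_interaction_lexicon() -> InteractionLexicon:
    """The shipped default dictionary: ~30 interaction verb lemmas in
    base/-s/-ed inflections plus nominal forms where natural."""
    text = resources.files("litcooc.data").joinpath("interaction_terms.txt").read_text("utf-8")
    return load_interaction_terms_from_text(text)


def load_interaction_terms_from_text(text: str) -> InteractionLexicon:
    return build_interaction_lexicon(
        line.strip() for line in text.splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    )


# ---------------------------------------------------------------------------
# User concepts
# ---------------------------------------------------------------------------

@dataclass
class ConceptLexicon:
    """Ordered, normalized, unique user concept phrases. May be empty,
    in which case concept analysis is skipped."""

    phrases: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.phrases)

    def __iter__(self):
        return iter(self.phrases)


def build_concept_lexicon(phrases: Iterable[str]) -> ConceptLexicon:
    seen: set[str] = set()
    out: list[str] = []
    for phrase in phrases:
        key = normalize_term(phrase)
        if key and key not in seen:
            seen.add(key)
            out.append(key)
    return ConceptLexicon(phrases=tuple(out))


def load_concepts(source: Union[PathLike, IO[str], str, None]) -> ConceptLexicon:
    """Load a concept list: one phrase per line. Normalization is
    case-fold plus whitespace collapse; order preserved, duplicates
    dropped. ``None`` or an empty source yields an empty lexicon.

    A plain string containing newlines is treated as inline content;
    any other string is a file path.
    """
    if source is None:
        return ConceptLexicon()
    if isinstance(source, str) and "\n" in source:
        lines: Iterable[str] = source.splitlines()
    else:
        lines = _read_lines(source)
    return build_concept_lexicon(lines)
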