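"""Abstract corpus input and sentence segmentation.

Reads abstract corpora from MEDLINE tagged-field text or PubMed efetch
XML, resolves plain PMID lists, and segments abstract text into
sentences with stable character offsets. The sentence is the context
unit for all downstream co-occurrence analysis, so offsets here are the
coordinate system of the whole pipeline: 0-based, half-open, relative
to the abstract body (title prepended).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Iterable, Iterator, Union

from Bio import Medline
from lxml import etree

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


class CorpusFormatError(ValueError):
    """Raised when an input file does not parse under its declared format."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SentenceSpan:
    """One sentence of an abstract body.

    ``start``/``end`` are 0-based half-open character offsets into the
    body; ``text`` equals ``body[start:end]``.
    """

    index: int
    start: int
    end: int
    text: str


@dataclass
class AbstractRecord:
    """One abstract: PMID, title, body text and its sentence spans.

    The title (when present) is prepended to the body, separated by a
    single space, so that entities mentioned only in titles are taggable.
    """

    pmid: str
    title: str
    body: str
    sentences: list[SentenceSpan] = field(default_factory=list)

    def sentence(self, index: int) -> SentenceSpan:
        return self.sentences[index]


@dataclass
class CorpusLoad:
    """Result of reading a corpus file: the records plus a skip count for
    articles that had no abstract text."""

    records: list[AbstractRecord]
    skipped: int = 0

    def __iter__(self) -> Iterator[AbstractRecord]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# PMID lists
# ---------------------------------------------------------------------------

def parse_pmid_list(source: Union[str, IO[str], Iterable[str]]) -> list[str]:
    """Parse a plain PMID list: one numeric token per line.

    Blank lines are allowed; duplicates are removed keeping the first
    occurrence; order is otherwise preserved.

    Raises
    ------
    CorpusFormatError
        If a non-numeric token is found, naming its line number.
    """
    if isinstance(source, str):
        lines: Iterable[str] = source.splitlines()
    else:
        lines = source
    seen: set[str] = set()
    out: list[str] = []
    for lineno, raw in enumerate(lines, start=1):
        token = raw.strip()
        if not token:
            continue
        if not token.isdigit():
            raise CorpusFormatError(
                f"line {lineno}: invalid PMID token {token!r} (digits expected)"
            )
        if token not in seen:
            seen.add(token)
            out.append(token)
    return out


# ---------------------------------------------------------------------------
# Sentence segmentation
# ---------------------------------------------------------------------------

def _load_default_abbreviations() -> frozenset[str]:
    text = resources.files("litcooc.data").joinpath("abbreviations.txt").read_text("utf-8")
    terms = set()
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.casefold())
    return frozenset(terms)


_DEFAULT_ABBREVIATIONS = _load_default_abbreviations()

# A boundary candidate: sentence-final punctuation, whitespace, then an
# uppercase letter or digit.
_BOUNDARY = re.compile(r"[.!?](?=\s+[A-Z0-9])")


def load_abbreviations(path: PathLike) -> frozenset[str]:
    """Load a user abbreviation guard list (one token per line, '#' comments)."""
    terms = set(_DEFAULT_ABBREVIATIONS)
    for line in Path(path).read_text("utf-8").splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            terms.add(line.casefold())
    return frozenset(terms)


def _is_abbreviation(text: str, dot_pos: int, abbreviations: frozenset[str]) -> bool:
    # Token ending at (and including) the period at dot_pos. Multi-word
    # guards ("et al.") are checked against a two-token tail as well.
    head = text[: dot_pos + 1]
    m = re.search(r"(\S+)$", head)
    if not m:
        return False
    last = m.group(1).casefold()
    if last in abbreviations:
        return True
    m2 = re.search(r"(\S+\s+\S+)$", head)
    return bool(m2) and re.sub(r"\s+", " ", m2.group(1).casefold()) in abbreviations


def segment_sentences(
    body: str, abbreviations: frozenset[str] | None = None
) -> list[SentenceSpan]:
    """Split text into sentence spans by rule.

    A split occurs after ``.``, ``!`` or ``?`` followed by whitespace and
    an uppercase letter or digit, unless the token ending at the
    punctuation is on the abbreviation guard list. Spans are trimmed of
    surrounding whitespace; every non-whitespace character of ``body``
    falls in exactly one span and ``text == body[start:end]`` holds.
    """
    if abbreviations is None:
        abbreviations = _DEFAULT_ABBREVIATIONS
    cuts: list[int] = []
    for m in _BOUNDARY.finditer(body):
        if body[m.start()] == "." and _is_abbreviation(body, m.start(), abbreviations):
            continue
        cuts.append(m.end())
    spans: list[SentenceSpan] = []
    prev = 0
    for cut in cuts + [len(body)]:
        segment = body[prev:cut]
        stripped = segment.strip()
        if stripped:
            start = prev + (len(segment) - len(segment.lstrip()))
            end = start + len(stripped)
            spans.append(
                SentenceSpan(index=len(spans), start=start, end=end, text=body[start:end])
            )
        prev = cut
    return spans


def make_record(
    pmid: str,
    title: str,
    abstract: str,
    abbreviations: frozenset[str] | None = None,
) -> AbstractRecord:
    """Assemble an AbstractRecord: title prepended to the abstract text
    (one separating space) and the result segmented into sentences."""
    title = title.strip()
    abstract = abstract.strip()
    body = f"{title} {abstract}" if title and abstract else (title or abstract)
    return AbstractRecord(
        pmid=pmid, title=title, body=body,
        sentences=segment_sentences(body, abbreviations),
    )


# ---------------------------------------------------------------------------
# Corpus readers
# ---------------------------------------------------------------------------

def _read_medline(path: Path) -> CorpusLoad:
    records: list[AbstractRecord] = []
    skipped = 0
    with open(path, encoding="utf-8") as handle:
        for rec in Medline.parse(handle):
            pmid = rec.get("PMID", "").strip()
            if not pmid:
                continue
            abstract = rec.get("AB", "")
            if isinstance(abstract, list):  # Medline joins, but be safe
                abstract = " ".join(abstract)
            if not abstract.strip():
                skipped += 1
                continue
            title = rec.get("TI", "")
            records.append(make_record(pmid, title, abstract))
    return CorpusLoad(records=records, skipped=skipped)


def _read_pubmed_xml(path: Path) -> CorpusLoad:
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusFormatError(f"not well-formed PubMed XML: {exc}") from exc
    records: list[AbstractRecord] = []
    skipped = 0
    for article in tree.iter("PubmedArticle"):
        pmid_el = article.find(".//MedlineCitation/PMID")
        if pmid_el is None or not (pmid_el.text or "").strip():
            continue
        pmid = pmid_el.text.strip()
        title = "".join(article.find(".//ArticleTitle").itertext()) \
            if article.find(".//ArticleTitle") is not None else ""
        texts = [
            "".join(el.itertext())
            for el in article.findall(".//Abstract/AbstractText")
        ]
        abstract = " ".join(t.strip() for t in texts if t and t.strip())
        if not abstract:
            skipped += 1
            continue
        records.append(make_record(pmid, title, abstract))
    return CorpusLoad(records=records, skipped=skipped)


def read_corpus(path: PathLike, format: str = "medline") -> CorpusLoad:
    """Read an abstract corpus file.

    Parameters
    ----------
    path : path to the corpus file.
    format : ``"medline"`` (tagged-field text, as returned by PubMed's
        "MEDLINE" display) or ``"pubmed-xml"`` (efetch XML).

    Returns one AbstractRecord per article that has a non-empty abstract;
    articles without abstract text are skipped and counted in
    ``CorpusLoad.skipped``. A corpus yielding zero records triggers a
    warning (the file may be in the wrong format).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "medline":
        load = _read_medline(path)
    elif format == "pubmed-xml":
        load = _read_pubmed_xml(path)
    else:
        raise ValueError(f"unknown corpus format {format!r}")
    if not load.records:
        logger.warning("corpus %s yielded zero records (format=%s)", path, format)
    return load


def select_pmids(load: CorpusLoad, pmids: Iterable[str]) -> CorpusLoad:
    """Restrict a corpus to a PMID list (a PMID list resolved against a
    local corpus file), preserving list order for PMIDs present."""
    by_id = {r.pmid: r for r in load.records}
    records = [by_id[p] for p in pmids if p in by_id]
    return CorpusLoad(records=records, skipped=load.skipped)
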