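"""Interaction network construction, filtering and export.

Networks are ``networkx.Graph`` objects. Entity nodes are keyed by the
normalized term; edges carry the best (minimum) co-occurrence type, the
instance support, source PMIDs, associated concepts and interaction
terms. Node labels map to official gene symbols when the mapping is
unambiguous; ambiguous terms (multiple candidate gene ids) keep the raw
term with an ``ambiguous`` flag — ambiguity is surfaced, never resolved
by guessing.

Concept nodes can be merged into the graph to relate parts of the
network to processes ("aggregation") or diseases, and the network can
be restricted to the sub-network annotated with one concept.

Exports: GraphML (full attributes, lossless round-trip), SIF (the best
type as relation label) and a TSV edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import networkx as nx

from .cooccur import CoOccurrence, PairSummary
from .lexicon import GeneLexicon

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

#: Node/edge attributes holding tuples, serialized as '|'-joined strings.
_NODE_LIST_ATTRS = ("raw_terms", "gene_ids")
_EDGE_LIST_ATTRS = ("pmids", "concepts", "interaction_terms")

CONCEPT_NODE_PREFIX = "concept:"


@dataclass
class NetworkFilter:
    """Display/build parameters.

    max_type : keep edges with best_type <= max_type (1 = strictest).
    concepts : if given, keep only edges annotated with at least one of
        these phrases.
    terms : if given, keep only edges incident to at least one of these
        term keys.
    use_official_symbols : label nodes by official gene symbol where the
        term maps to exactly one gene id; raw term otherwise.
    """

    max_type: int = 4
    concepts: frozenset[str] | None = None
    terms: frozenset[str] | None = None
    use_official_symbols: bool = True

    def __post_init__(self) -> None:
        if self.max_type not in (1, 2, 3, 4):
            raise ValueError(f"max_type must be 1..4, got {self.max_type}")


def _node_attrs(key: str, flt: NetworkFilter, lexicon: GeneLexicon | None) -> dict:
    gene_ids = lexicon.lookup(key) if lexicon is not None else ()
    ambiguous = len(gene_ids) > 1
    if flt.use_official_symbols and len(gene_ids) == 1 and lexicon is not None:
        label = lexicon.symbol_for(gene_ids[0])
    else:
        label = key
    return {
        "label": label,
        "raw_terms": (key,),
        "gene_ids": gene_ids,
        "kind": "entity",
        "ambiguous": ambiguous,
    }


def build_network(
    summaries: Iterable[PairSummary],
    flt: NetworkFilter | None = None,
    gene_lexicon: GeneLexicon | None = None,
) -> nx.Graph:
    """Build the interaction network from pair summaries.

    Only pairs passing the filter contribute; nodes appear only as
    endpoints of surviving edges. Raising ``max_type`` never removes
    nodes or edges (filter monotonicity).
    """
    flt = flt or NetworkFilter()
    g = nx.Graph()
    for s in sorted(summaries, key=lambda s: s.pair):
        if s.best_type > flt.max_type:
            continue
        if flt.concepts is not None and not (set(s.concepts) & flt.concepts):
            continue
        if flt.terms is not None and not (set(s.pair) & flt.terms):
            continue
        for key in s.pair:
            if key not in g:
                g.add_node(key, **_node_attrs(key, flt, gene_lexicon))
        g.add_edge(
            s.pair[0],
            s.pair[1],
            best_type=s.best_type,
            support=s.support,
            pmids=s.pmids,
            concepts=s.concepts,
            interaction_terms=s.interaction_terms,
        )
    return g


def add_concept_nodes(
    network: nx.Graph, cooccurrences: Iterable[CoOccurrence]
) -> nx.Graph:
    """Merge concept nodes into a copy of the network.

    Each concept phrase becomes one node linked to every entity node
    that shares at least one co-occurrence annotated with that concept.
    """
    g = network.copy()
    links: dict[tuple[str, str], list[CoOccurrence]] = {}
    for cooc in cooccurrences:
        for phrase in cooc.concepts:
            for key in cooc.pair:
                if key in network:
                    links.setdefault((phrase, key), []).append(cooc)
    for (phrase, key) in sorted(links):
        node_id = CONCEPT_NODE_PREFIX + phrase
        if node_id not in g:
            g.add_node(
                node_id,
                label=phrase,
                raw_terms=(phrase,),
                gene_ids=(),
                kind="concept",
                ambiguous=False,
            )
        instances = links[(phrase, key)]
        g.add_edge(
            node_id,
            key,
            best_type=min(c.cooc_type for c in instances),
            support=len(instances),
            pmids=tuple(sorted(set(c.pmid for c in instances))),
            concepts=(phrase,),
            interaction_terms=(),
        )
    return g


def concept_subnetwork(network: nx.Graph, phrase: str) -> nx.Graph:
    """Restrict to entity edges annotated with ``phrase`` plus their
    endpoints. An unknown phrase yields an empty network with a warning."""
    g = nx.Graph()
    for u, v, data in network.edges(data=True):
        if network.nodes[u].get("kind") == "concept" or \
           network.nodes[v].get("kind") == "concept":
            continue
        if phrase in data.get("concepts", ()):
            for n in (u, v):
                if n not in g:
                    g.add_node(n, **network.nodes[n])
            g.add_edge(u, v, **data)
    if not g.number_of_edges():
        logger.warning("concept %r annotates no edge in this network", phrase)
    return g


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------

def _stringified(network: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    for node in sorted(network.nodes):
        attrs = dict(network.nodes[node])
        for key in _NODE_LIST_ATTRS:
            attrs[key] = "|".join(attrs.get(key, ()))
        g.add_node(node, **attrs)
    for u, v in sorted(map(tuple, map(sorted, network.edges))):
        attrs = dict(network.edges[u, v])
        for key in _EDGE_LIST_ATTRS:
            attrs[key] = "|".join(attrs.get(key, ()))
        g.add_edge(u, v, **attrs)
    return g


def export_network(network: nx.Graph, path: PathLike, format: str = "graphml") -> None:
    """Write the network as ``graphml``, ``sif`` or ``tsv``.

    GraphML carries all node and edge attributes (tuple-valued
    attributes '|'-joined) and round-trips exactly through
    :func:`import_graphml`. SIF lines are ``term1 type<k> term2``. The
    TSV edge list aggregates one row per pair. Output is deterministic:
    nodes and edges are written in sorted order.
    """
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(_stringified(network), path, named_key_ids=True)
    elif format == "sif":
        with open(path, "w", encoding="utf-8", newline="") as handle:
            for u, v in sorted(map(tuple, map(sorted, network.edges))):
                t = network.edges[u, v].get("best_type", 4)
                handle.write(f"{u}\ttype{t}\t{v}\n")
    elif format == "tsv":
        with open(path, "w", encoding="utf-8", newline="") as handle:
            handle.write(
                "term1\tterm2\tbest_type\tsupport\tpmids\tconcepts\tinteraction_terms\n"
            )
            for u, v in sorted(map(tuple, map(sorted, network.edges))):
                d = network.edges[u, v]
                handle.write(
                    "\t".join(
                        [
                            u, v,
                            str(d.get("best_type", 4)),
                            str(d.get("support", 1)),
                            "|".join(d.get("pmids", ())),
                            "|".join(d.get("concepts", ())),
                            "|".join(d.get("interaction_terms", ())),
                        ]
                    )
                    + "\n"
                )
    else:
        raise ValueError(f"unknown export format {format!r} (graphml, sif, tsv)")


def import_graphml(path: PathLike) -> nx.Graph:
    """Read a GraphML export back, restoring tuple-valued attributes."""
    raw = nx.read_graphml(str(path))
    g = nx.Graph()
    for node, attrs in raw.nodes(data=True):
        attrs = dict(attrs)
        for key in _NODE_LIST_ATTRS:
            if key in attrs:
                attrs[key] = tuple(x for x in attrs[key].split("|") if x)
        g.add_node(node, **attrs)
    for u, v, attrs in raw.edges(data=True):
        attrs = dict(attrs)
        for key in _EDGE_LIST_ATTRS:
            if key in attrs:
                attrs[key] = tuple(x for x in attrs[key].split("|") if x)
        g.add_edge(u, v, **attrs)
    return g
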