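"""Search, neighborhood extraction, filtering and export of subgraphs.

This is the library layer behind a graph-exploration service: all
behavior lives here (and in the CLI) so nothing ever needs a running
server.  Searches return entities ranked by degree; a neighborhood query
induces the subgraph on the hits plus their direct neighbors; node/edge
type filters drop nodes of unselected types *except* query nodes, which
remain as long as they keep at least one edge; and any subgraph can be
rendered as a deterministic text summary, a JSON API object
(``/api/<search type>/<search query>``) or a tab-delimited edge table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Protocol, Sequence

from .corpus_io import Document, parse_provenance_key
from .kg_analytics import Edge, KnowledgeGraph, degree_distribution

QUERY_MODES = ("normal", "substring", "author", "title")


class QueryError(ValueError):
    pass


@dataclass(frozen=True)
class Query:
    mode: str
    term: str

    def __post_init__(self) -> None:
        if self.mode not in QUERY_MODES:
            raise QueryError(f"unknown query mode {self.mode!r}")
        if not self.term:
            raise QueryError("query term must be non-empty")


@dataclass
class Subgraph:
    kg: KnowledgeGraph
    node_ids: set[str]
    edge_keys: set[tuple[str, str, str]]
    query_ids: set[str] = field(default_factory=set)

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_papers(self) -> int:
        pmids: set[str] = set()
        for key in self.edge_keys:
            for prov in self.kg.edges[key].provenance:
                pmids.add(parse_provenance_key(prov).pmid)
        return len(pmids)

    def edges(self) -> list[Edge]:
        return [self.kg.edges[k] for k in sorted(self.edge_keys)]


def _rank(kg: KnowledgeGraph, names: set[str]) -> list[str]:
    # multiple hits are ranked by degree (hubs first), then name
    degrees = degree_distribution(kg).degrees if names else {}
    return sorted(names, key=lambda n: (-degrees.get(n, 0), n))


def search(
    kg: KnowledgeGraph,
    query: Query,
    corpus: Sequence[Document] | None = None,
) -> list[str]:
    """Return matching entity names, ranked by degree.

    ``normal`` matches the canonical name or any surface form
    case-insensitively and exactly; ``substring`` by containment;
    ``title`` looks a PubMed ID up in edge provenance; ``author``
    requires a corpus whose documents carry author metadata.
    An absent term yields an empty list, not an error.
    """
    term = query.term.casefold()
    hits: set[str] = set()
    if query.mode == "normal":
        for ent in kg.entities.values():
            if term == ent.name.casefold() or any(
                term == s.casefold() for s in ent.surface_forms
            ):
                hits.add(ent.name)
    elif query.mode == "substring":
        for ent in kg.entities.values():
            if term in ent.name.casefold() or any(
                term in s.casefold() for s in ent.surface_forms
            ):
                hits.add(ent.name)
    elif query.mode == "title":
        for edge in kg.edges.values():
            if any(parse_provenance_key(p).pmid == query.term for p in edge.provenance):
                hits.update((edge.source, edge.target))
    elif query.mode == "author":
        if corpus is None or all(doc.authors is None for doc in corpus):
            raise QueryError(
                "author search requires a corpus with author metadata; "
                "none is available, so this mode is disabled"
            )
        pmids = {
            doc.pmid
            for doc in corpus
            if doc.authors and any(term in a.casefold() for a in doc.authors)
        }
        for edge in kg.edges.values():
            if any(parse_provenance_key(p).pmid in pmids for p in edge.provenance):
                hits.update((edge.source, edge.target))
    return _rank(kg, hits)


def neighborhood(kg: KnowledgeGraph, entity_ids: Sequence[str]) -> Subgraph:
    """Induced subgraph on the given entities plus all direct neighbors."""
    for eid in entity_ids:
        if eid not in kg.entities:
            raise QueryError(f"unknown entity id {eid!r}")
    nodes = set(entity_ids)
    for eid in entity_ids:
        nodes |= kg.neighbors(eid)
    edges = {k for k in kg.edges if k[0] in nodes and k[2] in nodes}
    return Subgraph(kg, nodes, edges, query_ids=set(entity_ids))


def filter_subgraph(
    sub: Subgraph,
    node_types: Sequence[str] | None = None,
    edge_relations: Sequence[str] | None = None,
) -> Subgraph:
    """Restrict a subgraph to selected node types and edge relations.

    Query nodes are retained regardless of type as long as they keep at
    least one surviving edge; when every edge of a query node is filtered
    away the node is dropped too (so an empty selection yields an empty
    result).  Idempotent; selecting everything is the identity.
    """
    kg = sub.kg
    keep_types = None if node_types is None else set(node_types)
    keep_rels = None if edge_relations is None else set(edge_relations)

    typed_ok = {
        n
        for n in sub.node_ids
        if keep_types is None or kg.entities[n].primary_type in keep_types
    }
    candidates = typed_ok | sub.query_ids
    edges = {
        k
        for k in sub.edge_keys
        if k[0] in candidates
        and k[2] in candidates
        and (keep_rels is None or k[1] in keep_rels)
    }
    connected = {k[0] for k in edges} | {k[2] for k in edges}
    # a node already isolated in the input was not *made* dangling by this
    # filter and is kept (so selecting everything is the identity)
    was_isolated = {
        n for n in sub.node_ids if not any(n in (k[0], k[2]) for k in sub.edge_keys)
    }
    nodes = (typed_ok & (connected | was_isolated)) | (sub.query_ids & connected)
    return Subgraph(kg, nodes, edges, query_ids=set(sub.query_ids))


def render_summary(sub: Subgraph) -> str:
    """Deterministic text summary grouped by relation.

    One line per edge, ``A regulates B (pmid_key, ...)``, ordered by
    relation, then source, then target; every statement cites the
    provenance keys of the articles asserting it.
    """
    lines: list[str] = []
    by_rel: dict[str, list[Edge]] = {}
    for edge in sub.edges():
        by_rel.setdefault(edge.relation, []).append(edge)
    for rel in sorted(by_rel):
        lines.append(f"[{rel}]")
        for edge in sorted(by_rel[rel], key=lambda e: (e.source, e.target)):
            provs = ", ".join(edge.provenance)
            lines.append(f"{edge.source} {rel} {edge.target} ({provs})")
    return "\n".join(lines)


@dataclass
class Verdict:
    supported: bool
    sentences: list[str]


class ValidatorBackend(Protocol):
    def validate(self, edge: Edge, source_text: str) -> Verdict: ...


class CooccurrenceValidator:
    """Mock edge validator: an edge is supported when both endpoints (any
    of their surface forms) co-occur within one sentence of the source
    text."""

    def __init__(self, kg: KnowledgeGraph) -> None:
        self.kg = kg

    def validate(self, edge: Edge, source_text: str) -> Verdict:
        def surfaces(name: str) -> list[str]:
            ent = self.kg.entities.get(name)
            forms = set(ent.surface_forms) if ent else set()
            forms.add(name)
            return [f.casefold() for f in forms]

        src_forms = surfaces(edge.source)
        tgt_forms = surfaces(edge.target)
        hits: list[str] = []
        for sentence in re.split(r"(?<=\.)\s+", source_text.strip()):
            folded = sentence.casefold()
            if any(s in folded for s in src_forms) and any(t in folded for t in tgt_forms):
                hits.append(sentence)
        return Verdict(supported=bool(hits), sentences=hits)


def validate_edge(
    edge: Edge, source_text: str | None, validator: ValidatorBackend
) -> Verdict:
    if not source_text:
        raise QueryError(f"no source text available for edge {edge.key}")
    return validator.validate(edge, source_text)


def api_route(query: Query) -> str:
    return f"/api/{query.mode}/{query.term}"


def to_json(sub: Subgraph) -> dict:
    """JSON API object: relationships with definitions, evidence basis,
    original and resolved names, PubMed IDs and the text summary."""
    kg = sub.kg
    nodes = [
        {
            "name": n,
            "type": kg.entities[n].primary_type,
            "surface_forms": kg.entities[n].surface_forms,
            "definitions": kg.entities[n].definitions,
        }
        for n in sorted(sub.node_ids)
    ]
    edges = [
        {
            "source": e.source,
            "relation": e.relation,
            "original_relations": e.original_relations,
            "target": e.target,
            "provenance": e.provenance,
            "pmids": e.pmids,
            "evidence": e.evidence,
        }
        for e in sub.edges()
    ]
    return {
        "n_nodes": sub.n_nodes,
        "n_papers": sub.n_papers,
        "query": sorted(sub.query_ids),
        "nodes": nodes,
        "edges": edges,
        "summary": render_summary(sub),
    }


def to_tsv(sub: Subgraph) -> str:
    """Edge table with columns source, relation, target, pmids, evidence."""
    lines = ["source\trelation\ttarget\tpmids\tevidence"]
    for e in sub.edges():
        lines.append(
            "\t".join(
                [e.source, e.relation, e.target, ";".join(e.pmids), ";".join(e.evidence)]
            )
        )
    return "\n".join(lines) + "\n"


def dumps_json(sub: Subgraph) -> str:
    return json.dumps(to_json(sub), indent=1)
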