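"""Comparison of knowledge-graph gene-gene edges with external edge lists.

Supports the edge-list dialects of curated gene-regulatory networks
(directed transcription-factor -> target pairs, AGRIS-style), protein-
protein interaction catalogues (undirected pairs, BioGRID-style) and
scored association networks (STRING-style, filtered by a score
threshold).  Overlap is computed on normalized gene-pair identity only;
relation labels are carried along as annotations but ignored for
membership, so a Venn region counts edges, not labeled statements.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

_AGI_RE = re.compile(r"^[Aa][Tt](?P<chrom>[1-5CMcm])[Gg](?P<num>\d{5})$")

#: Relation classes used to split knowledge-graph gene-gene edges before
#: comparison: physical-interaction-like relations (compared undirected
#: against PPI catalogues) and regulation-like relations (compared
#: directionally against GRN databases).  Editable configuration.
INTERACTION_CLASS: tuple[str, ...] = (
    "interacts with",
    "forms a complex with",
    "forms complex with",
    "complexes with",
)
REGULATION_CLASS: tuple[str, ...] = (
    "regulate",
    "regulates",
    "binds",
    "activates",
    "represses",
    "targets",
)


class EdgeListError(ValueError):
    pass


def normalize_gene_id(text: str) -> str:
    """Canonicalize a gene identifier.

    AGI locus codes are uppercased to ``AT#G#####`` (``At4g32410`` ->
    ``AT4G32410``); anything else is case-folded to upper case
    (``myb46`` -> ``MYB46``).
    """
    m = _AGI_RE.match(text.strip())
    if m:
        return f"AT{m.group('chrom').upper()}G{m.group('num')}"
    return text.strip().upper()


def is_agi_id(text: str) -> bool:
    return _AGI_RE.match(text.strip()) is not None


@dataclass(frozen=True)
class EdgeRecord:
    a: str
    b: str
    relation: str | None = None
    score: float | None = None
    annotations: tuple[str, ...] = ()


@dataclass
class EdgeList:
    """A set of gene-gene edges, directional or unidirectional.

    Endpoints are normalized at construction; records whose normalized
    key duplicates an earlier one are collapsed (first record wins).
    """

    records: list[EdgeRecord] = field(default_factory=list)
    directed: bool = True
    name: str = ""

    def __post_init__(self) -> None:
        seen: set = set()
        unique: list[EdgeRecord] = []
        for rec in self.records:
            rec = EdgeRecord(
                normalize_gene_id(rec.a),
                normalize_gene_id(rec.b),
                rec.relation,
                rec.score,
                rec.annotations,
            )
            key = self._key(rec.a, rec.b)
            if key in seen:
                continue
            seen.add(key)
            unique.append(rec)
        self.records = unique

    def _key(self, a: str, b: str):
        return (a, b) if self.directed else tuple(sorted((a, b)))

    def keys(self) -> set:
        return {self._key(r.a, r.b) for r in self.records}

    def __len__(self) -> int:
        return len(self.records)


def read_edge_list(
    path: str | Path,
    directed: bool = True,
    has_header: bool = False,
    name: str = "",
) -> EdgeList:
    """Read a two-column-minimum TSV edge list.

    Column order: gene A, gene B, then optionally a relation label and a
    numeric score; any further columns are preserved as annotations.
    """
    records: list[EdgeRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if has_header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise EdgeListError(f"{path}: line {lineno} has fewer than 2 columns")
            relation = fields[2] if len(fields) > 2 and fields[2] else None
            score = None
            if len(fields) > 3 and fields[3]:
                try:
                    score = float(fields[3])
                except ValueError as exc:
                    raise EdgeListError(f"{path}: bad score on line {lineno}") from exc
            records.append(
                EdgeRecord(fields[0], fields[1], relation, score, tuple(fields[4:]))
            )
    return EdgeList(records, directed=directed, name=name or str(path))


def write_edge_list(el: EdgeList, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in el.records:
            row = [r.a, r.b, r.relation or "", "" if r.score is None else repr(r.score)]
            row.extend(r.annotations)
            fh.write("\t".join(row).rstrip("\t") + "\n")


def kg_gene_edges(kg, directed: bool = True, agi_only: bool = False) -> EdgeList:
    """Project a knowledge graph onto a gene-gene edge list.

    Keeps edges whose endpoints both look like gene identifiers (AGI
    pattern) when ``agi_only``; otherwise keeps edges between entities
    whose primary type contains "gene"."""
    records = []
    for edge in kg.edges.values():
        if agi_only:
            ok = is_agi_id(edge.source) and is_agi_id(edge.target)
        else:
            ok = all(
                "gene" in kg.entities[n].primary_type for n in (edge.source, edge.target)
            )
        if ok:
            records.append(EdgeRecord(edge.source, edge.target, edge.relation))
    return EdgeList(records, directed=directed, name="connectome")


def to_unidirectional(el: EdgeList) -> EdgeList:
    """Disregard gene order: each pair is stored endpoint-sorted and
    duplicates collapse, so the result is never larger than the input."""
    records = [
        EdgeRecord(*sorted((r.a, r.b)), relation=r.relation, score=r.score,
                   annotations=r.annotations)
        for r in el.records
    ]
    return EdgeList(records, directed=False, name=el.name)


@dataclass
class OverlapReport:
    """Exact Venn partition of 2 or 3 edge lists.

    ``region_counts`` is keyed by membership tuples, e.g. ``(True, False)``
    for edges only in the first list.  Region counts sum to the size of
    the union and are symmetric under input permutation.
    """

    labels: tuple[str, ...]
    region_counts: dict[tuple[bool, ...], int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())

    def size(self, label: str) -> int:
        i = self.labels.index(label)
        return sum(n for key, n in self.region_counts.items() if key[i])

    @property
    def intersection_count(self) -> int:
        return self.region_counts.get((True,) * len(self.labels), 0)

    def percent_shared_of(self, label: str) -> float:
        """Percentage of ``label``'s edges found in all lists, to one
        decimal — the number printed next to a Venn diagram."""
        total = self.size(label)
        if total == 0:
            raise EdgeListError(f"edge list {label!r} is empty")
        return round(100.0 * self.intersection_count / total, 1)

    def format_percent(self, label: str) -> str:
        return f"{self.percent_shared_of(label):.1f}%"

    @classmethod
    def from_pair_counts(
        cls, labels: tuple[str, str], only_a: int, only_b: int, both: int
    ) -> "OverlapReport":
        return cls(
            labels,
            {(True, False): only_a, (False, True): only_b, (True, True): both},
        )


def overlap(lists: Sequence[EdgeList], labels: Sequence[str] | None = None) -> OverlapReport:
    """Exact Venn partition on normalized edge keys of 2 or 3 lists."""
    if len(lists) not in (2, 3):
        raise EdgeListError("overlap takes 2 or 3 edge lists")
    if len({el.directed for el in lists}) != 1:
        raise EdgeListError("edge lists mix directional conventions")
    labels = tuple(labels) if labels else tuple(
        el.name or f"list{i}" for i, el in enumerate(lists)
    )
    keysets = [el.keys() for el in lists]
    union = set().union(*keysets)
    counts: dict[tuple[bool, ...], int] = {
        key: 0 for key in product((False, True), repeat=len(lists)) if any(key)
    }
    for edge in union:
        membership = tuple(edge in ks for ks in keysets)
        counts[membership] += 1
    return OverlapReport(labels, counts)


def partition_by_relation_class(
    el: EdgeList, relation_class: Iterable[str]
) -> tuple[EdgeList, EdgeList]:
    """Split an edge list into (in-class, out-of-class) by relation label.

    Membership is exact case-folded equality against the class list; an
    empty class puts everything out-of-class.  Unlabeled edges are
    out-of-class."""
    members = {r.casefold() for r in relation_class}
    in_recs, out_recs = [], []
    for rec in el.records:
        if rec.relation is not None and rec.relation.casefold() in members:
            in_recs.append(rec)
        else:
            out_recs.append(rec)
    return (
        EdgeList(in_recs, directed=el.directed, name=f"{el.name}:in-class"),
        EdgeList(out_recs, directed=el.directed, name=f"{el.name}:out-of-class"),
    )


def score_filter(el: EdgeList, threshold: float) -> EdgeList:
    """Keep edges with score strictly above the threshold (e.g. STRING
    text-mining score > 700).  Missing scores are an error."""
    for rec in el.records:
        if rec.score is None:
            raise EdgeListError(f"edge {rec.a}-{rec.b} has no score")
    kept = [r for r in el.records if r.score > threshold]
    return EdgeList(kept, directed=el.directed, name=el.name)


def sample_edges(el: EdgeList, n: int, seed: int) -> EdgeList:
    """Uniform sample without replacement, deterministic per seed; used to
    draw edges for manual curation."""
    if n > len(el.records):
        raise EdgeListError(f"cannot sample {n} of {len(el.records)} edges")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(el.records), size=n, replace=False)
    return EdgeList([el.records[i] for i in idx], directed=el.directed, name=el.name)


def curation_sheet(el: EdgeList, sources: dict | None = None) -> str:
    """TSV curation sheet: one row per sampled edge with a source-text
    reference column for the curator to fill or verify."""
    lines = ["gene_a\tgene_b\trelation\tsource_ref"]
    for r in el.records:
        ref = (sources or {}).get((r.a, r.b), "")
        lines.append("\t".join([r.a, r.b, r.relation or "", ref]))
    return "\n".join(lines) + "\n"
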