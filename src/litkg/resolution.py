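"""Three-tier disambiguation of types, entities and relations.

The knowledge graph extracted from free text is redundant: the same
entity appears under casing, plural, abbreviation and synonym variants,
and the same relation under several tenses and the passive voice.  This
module implements a three-tier resolution protocol:

1. **Type resolution** — the most frequent entity types form a reference
   set; every remaining type is either mapped onto one of its nearest
   reference types (cosine similarity of text embeddings) or promoted
   into the reference set.
2. **Entity resolution** — every entity record (name, resolved type,
   definition) is embedded; embeddings are recursively bisected with
   k-means until clusters hold at most ``cap`` items (so a language-model
   resolver can fit a cluster in one context window); each cluster is
   sub-clustered by a :class:`ResolverBackend`, validated, and every
   member mapped to its sub-cluster representative.
3. **Relation resolution** — relation surfaces are embedded in their type
   context (``"<source type> <relation> <target type>"``) and clustered
   the same way.

A deterministic rule-based canonicalization pass (case folding, passive
-> active rewriting with source/target swap, most-frequent-form synonym
collapsing over the most common surfaces) runs before the embedding
tiers.  Both the embedding and resolver backends are pluggable; the
shipped mocks (hashed character-trigram embedder, synonym-table and
case-folding resolvers) are deterministic and require no network.
"""

from __future__ import annotations

import json
import zlib
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Protocol, Sequence

import numpy as np

from . import grammar
from .extraction import RawTriple

DEFAULT_CLUSTER_CAP = 30
DEFAULT_REFERENCE_SIZE = 30
DEFAULT_TYPE_NEIGHBORS = 10
DEFAULT_TOP_N_RULES = 100


class ResolutionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# embedding backend


class EmbeddingBackend(Protocol):
    dimension: int

    def embed(self, text: str) -> np.ndarray: ...


class HashedNgramEmbedder:
    """Deterministic mock embedder: hashed character-trigram frequencies.

    Case-folded trigrams (with boundary padding) are hashed into a fixed
    number of buckets and the count vector is L2-normalized, so casing
    and plural variants of a name land nearby while unrelated names do
    not.  Dimension is configurable; 256 buckets suffice for corpus-scale
    vocabularies while keeping hash collisions tolerable.
    """

    def __init__(self, dimension: int = 256, n: int = 3) -> None:
        self.dimension = dimension
        self.n = n
        self._cache: dict[str, np.ndarray] = {}

    def embed(self, text: str) -> np.ndarray:
        vec = self._cache.get(text)
        if vec is not None:
            return vec
        folded = f" {text.casefold()} "
        counts = np.zeros(self.dimension)
        for i in range(max(len(folded) - self.n + 1, 0)):
            gram = folded[i : i + self.n]
            counts[zlib.crc32(gram.encode("utf-8")) % self.dimension] += 1.0
        norm = np.linalg.norm(counts)
        if norm > 0:
            counts /= norm
        self._cache[text] = counts
        return counts


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(a @ b / (na * nb))


# ---------------------------------------------------------------------------
# resolver backend contract and mocks


@dataclass
class EntityRecord:
    """One item offered to the resolver: a surface form in context."""

    name: str
    type: str = ""
    definition: str = ""
    count: int = 1


@dataclass
class SubCluster:
    members: list[EntityRecord]
    representative: EntityRecord


@dataclass
class ValidationResult:
    valid: bool
    subclusters: list[SubCluster] | None = None  # corrections when invalid


class ResolverBackend(Protocol):
    def subcluster(self, items: Sequence[EntityRecord]) -> list[SubCluster]: ...

    def validate(self, cluster: SubCluster) -> ValidationResult: ...

    def resolve_type(self, raw_type: str, candidates: Sequence[str]) -> str | None:
        """Map ``raw_type`` onto one of ``candidates`` or return None to
        promote it into the reference set."""
        ...


def _pick_representative(members: Sequence[EntityRecord], canonical: str | None) -> EntityRecord:
    for m in members:
        if canonical is not None and m.name == canonical:
            return m
    return sorted(members, key=lambda m: (-m.count, m.name))[0]


class IdentityResolver:
    """Case-folding resolver: groups surface forms that differ only by
    casing; everything else stays separate."""

    def _canon(self, name: str) -> str:
        return name.casefold()

    def subcluster(self, items: Sequence[EntityRecord]) -> list[SubCluster]:
        groups: dict[str, list[EntityRecord]] = {}
        for item in items:
            groups.setdefault(self._canon(item.name), []).append(item)
        return [
            SubCluster(members, _pick_representative(members, canon))
            for canon, members in sorted(groups.items())
        ]

    def validate(self, cluster: SubCluster) -> ValidationResult:
        canons = {self._canon(m.name) for m in cluster.members}
        if len(canons) <= 1:
            return ValidationResult(valid=True)
        return ValidationResult(valid=False, subclusters=self.subcluster(cluster.members))

    def resolve_type(self, raw_type: str, candidates: Sequence[str]) -> str | None:
        folded = raw_type.casefold()
        for cand in candidates:
            if cand.casefold() == folded:
                return cand
        return None


class SynonymTableResolver(IdentityResolver):
    """Synonym-aware resolver driven by an explicit surface -> canonical
    table, the shipped stand-in for a fine-tuned language model.

    Unknown surfaces fall back to case folding.
    """

    def __init__(self, table: Mapping[str, str]) -> None:
        self.table = dict(table)
        self._folded = {k.casefold(): v for k, v in self.table.items()}

    def _canon(self, name: str) -> str:
        if name in self.table:
            return self.table[name]
        return self._folded.get(name.casefold(), name.casefold())

    def resolve_type(self, raw_type: str, candidates: Sequence[str]) -> str | None:
        canon = self._canon(raw_type)
        for cand in candidates:
            if cand == canon or self._canon(cand) == canon:
                return cand
        return super().resolve_type(raw_type, candidates)


class AlwaysNewResolver(IdentityResolver):
    """Degenerate resolver that never merges types (each becomes its own
    reference); useful as a worst-case baseline."""

    def resolve_type(self, raw_type: str, candidates: Sequence[str]) -> str | None:
        return None


# ---------------------------------------------------------------------------
# capped iterative k-means


@dataclass
class ClusterNode:
    indices: np.ndarray
    children: list["ClusterNode"] = field(default_factory=list)
    forced_split: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class ClusterTree:
    root: ClusterNode
    cap: int
    seed: int

    def leaves(self) -> list[np.ndarray]:
        out: list[np.ndarray] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.indices)
            else:
                stack.extend(reversed(node.children))
        return out

    @property
    def any_forced(self) -> bool:
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.forced_split:
                return True
            stack.extend(node.children)
        return False


def _child_seed(seed: int, child: int) -> int:
    return (seed * 31 + child + 1) % (2**31)


def capped_kmeans(embeddings: np.ndarray, cap: int = DEFAULT_CLUSTER_CAP, seed: int = 0) -> ClusterTree:
    """Recursively bisect with 2-means until every leaf holds <= cap items.

    Bisection (rather than a data-dependent k) gives a deterministic,
    balanced tree with bounded depth; each node re-seeds k-means from
    (parent seed, child index).  A cluster of identical points larger
    than the cap cannot be separated by k-means and is split arbitrarily
    in half, flagged ``forced_split``, to guarantee termination.
    """
    from sklearn.cluster import KMeans

    embeddings = np.asarray(embeddings, dtype=float)
    if embeddings.ndim != 2 or len(embeddings) == 0:
        raise ValueError("need a non-empty 2-D embedding matrix")
    if cap < 1:
        raise ValueError("cap must be >= 1")

    def split(indices: np.ndarray, node_seed: int) -> ClusterNode:
        node = ClusterNode(indices=indices)
        if len(indices) <= cap:
            return node
        X = embeddings[indices]
        forced = False
        if np.allclose(X, X[0]):
            labels = np.zeros(len(indices), dtype=int)
            labels[len(indices) // 2 :] = 1
            forced = True
        else:
            km = KMeans(n_clusters=2, n_init=10, random_state=node_seed % (2**31))
            labels = km.fit_predict(X)
            if len(np.unique(labels)) < 2:
                labels = np.zeros(len(indices), dtype=int)
                labels[len(indices) // 2 :] = 1
                forced = True
        node.forced_split = forced
        for child in (0, 1):
            sub = indices[labels == child]
            node.children.append(split(sub, _child_seed(node_seed, child)))
        return node

    root = split(np.arange(len(embeddings)), seed)
    return ClusterTree(root=root, cap=cap, seed=seed)


# ---------------------------------------------------------------------------
# type resolution


@dataclass
class TypeResolutionState:
    reference_types: list[str]
    mapping: dict[str, str]
    k_neighbors: int = DEFAULT_TYPE_NEIGHBORS

    def resolve(self, raw_type: str) -> str:
        return self.mapping.get(raw_type, raw_type)


def resolve_types(
    type_frequency: Mapping[str, int],
    embedder: EmbeddingBackend,
    resolver: ResolverBackend,
    reference_size: int = DEFAULT_REFERENCE_SIZE,
    k_neighbors: int = DEFAULT_TYPE_NEIGHBORS,
) -> TypeResolutionState:
    """Resolve raw entity types against a growing reference set.

    The ``reference_size`` most frequent types seed the reference set to
    preserve their integrity; remaining types are processed in descending
    frequency (ties lexicographic), each offered its ``k_neighbors``
    closest reference types by cosine similarity, and either mapped or
    promoted into the reference set.
    """
    if not type_frequency:
        raise ResolutionError("type frequency table is empty")
    order = sorted(type_frequency.items(), key=lambda kv: (-kv[1], kv[0]))
    reference = [t for t, _ in order[:reference_size]]
    mapping = {t: t for t in reference}
    try:
        ref_vecs = [embedder.embed(t) for t in reference]
    except Exception as exc:
        raise ResolutionError(f"embedder failed on reference types: {exc}") from exc
    for raw, _ in order[reference_size:]:
        try:
            vec = embedder.embed(raw)
        except Exception as exc:
            raise ResolutionError(f"embedder failed on type {raw!r}: {exc}") from exc
        sims = np.array([cosine_similarity(vec, rv) for rv in ref_vecs])
        top = np.argsort(-sims, kind="stable")[:k_neighbors]
        candidates = [reference[i] for i in top]
        resolved = resolver.resolve_type(raw, candidates)
        if resolved is None:
            reference.append(raw)
            ref_vecs.append(vec)
            mapping[raw] = raw
        else:
            if resolved not in reference:
                raise ResolutionError(
                    f"resolver mapped {raw!r} to non-reference type {resolved!r}"
                )
            mapping[raw] = resolved
    return TypeResolutionState(reference, mapping, k_neighbors)


# ---------------------------------------------------------------------------
# entity and relation resolution


def _cluster_round(
    records: Sequence[EntityRecord],
    texts: Sequence[str],
    embedder: EmbeddingBackend,
    resolver: ResolverBackend,
    cap: int,
    seed: int,
) -> dict[str, str]:
    X = np.vstack([embedder.embed(t) for t in texts])
    tree = capped_kmeans(X, cap=cap, seed=seed)
    mapping: dict[str, str] = {}
    for leaf_no, leaf in enumerate(tree.leaves()):
        items = [records[i] for i in leaf]
        subclusters = resolver.subcluster(items)
        _check_partition(items, subclusters, leaf_no)
        final: list[SubCluster] = []
        for sub in subclusters:
            verdict = resolver.validate(sub)
            if verdict.valid:
                final.append(sub)
            else:
                corrected = verdict.subclusters or []
                _check_partition(sub.members, corrected, leaf_no)
                final.extend(corrected)
        for sub in final:
            rep = sub.representative.name
            for member in sub.members:
                mapping[member.name] = rep
    # canonical forms map to themselves
    for rep in list(mapping.values()):
        mapping.setdefault(rep, rep)
    return mapping


MAX_RESOLUTION_ROUNDS = 4
NEIGHBOR_CANDIDATES = 8
MAX_NEIGHBOR_PASSES = 5


def _neighbor_pass(
    records: Sequence[EntityRecord],
    texts: Sequence[str],
    embedder: EmbeddingBackend,
    resolver: ResolverBackend,
) -> dict[str, str]:
    """High-recall candidate generation: offer every representative with
    its nearest neighbors to the resolver, which alone decides merges.

    Leaf boundaries of the capped clustering are k-means artifacts; two
    variants of one entity can end up as representatives of different
    leaves.  Presenting each representative with its nearest other
    representatives (cosine over the same embeddings) lets the resolver
    repair such splits; a resolver that recognizes no synonyms merges
    nothing, so the pass is conservative by construction.
    """
    X = np.vstack([embedder.embed(t) for t in texts])
    sims = X @ X.T
    np.fill_diagonal(sims, -np.inf)
    mapping: dict[str, str] = {}
    m = min(NEIGHBOR_CANDIDATES, len(records) - 1)
    if m <= 0:
        return mapping
    for i in range(len(records)):
        neighbors = np.argsort(-sims[i], kind="stable")[:m]
        group = [records[i]] + [records[j] for j in neighbors]
        for sub in resolver.subcluster(group):
            if len(sub.members) < 2:
                continue
            rep = sub.representative.name
            for member in sub.members:
                if member.name != rep:
                    mapping[member.name] = rep
    # path-compress chains a -> b -> c
    def follow(name: str, seen: set[str]) -> str:
        while name in mapping and name not in seen:
            seen.add(name)
            name = mapping[name]
        return name

    return {name: follow(name, set()) for name in mapping}


def _cluster_and_map(
    records: Sequence[EntityRecord],
    texts: Sequence[str],
    embedder: EmbeddingBackend,
    resolver: ResolverBackend,
    cap: int,
    seed: int,
) -> dict[str, str]:
    """Iterate clustering + sub-cluster resolution to a fixpoint.

    One clustering pass can strand members of the same group in different
    leaves (the leaf boundary is a k-means artifact, not a semantic one),
    so the representatives of each round are fed back through clustering
    — with a freshly derived seed, hence different leaf boundaries —
    until no further merges occur.  The per-round maps are composed into
    one surface -> canonical map.
    """
    mapping = {r.name: r.name for r in records}
    cur_records = list(records)
    cur_texts = list(texts)
    for rnd in range(MAX_RESOLUTION_ROUNDS):
        round_map = _cluster_round(
            cur_records, cur_texts, embedder, resolver, cap, _child_seed(seed, rnd)
        )
        mapping = {
            surface: round_map.get(rep, rep) for surface, rep in mapping.items()
        }
        # collapse to one record per surviving representative
        merged: dict[str, EntityRecord] = {}
        merged_texts: dict[str, str] = {}
        for rec, text in zip(cur_records, cur_texts):
            rep = round_map.get(rec.name, rec.name)
            if rep not in merged:
                is_rep = rec.name == rep
                merged[rep] = EntityRecord(rep, rec.type, rec.definition, rec.count)
                merged_texts[rep] = text if is_rep else ""
            else:
                merged[rep].count += rec.count
            if rec.name == rep:
                merged_texts[rep] = text
        converged = len(merged) == len(cur_records)
        cur_records = list(merged.values())
        cur_texts = [merged_texts[r.name] or f"{r.name} | {r.type} | {r.definition}"
                     for r in cur_records]
        if converged:
            break
    # repair residual cross-leaf splits among the surviving representatives
    for _ in range(MAX_NEIGHBOR_PASSES):
        extra = _neighbor_pass(cur_records, cur_texts, embedder, resolver)
        if not extra:
            break
        mapping = {s: extra.get(rep, rep) for s, rep in mapping.items()}
        merged2: dict[str, EntityRecord] = {}
        texts2: dict[str, str] = {}
        for rec, text in zip(cur_records, cur_texts):
            rep = extra.get(rec.name, rec.name)
            if rep not in merged2:
                merged2[rep] = EntityRecord(rep, rec.type, rec.definition, rec.count)
                texts2[rep] = text if rec.name == rep else ""
            else:
                merged2[rep].count += rec.count
            if rec.name == rep:
                texts2[rep] = text
        cur_records = list(merged2.values())
        cur_texts = [texts2[r.name] or f"{r.name} | {r.type} | {r.definition}"
                     for r in cur_records]
    return mapping


def _check_partition(
    items: Sequence[EntityRecord], subclusters: Sequence[SubCluster], leaf_no: int
) -> None:
    got = sorted(m.name for sub in subclusters for m in sub.members)
    want = sorted(item.name for item in items)
    if got != want:
        raise ResolutionError(f"resolver output is not a partition of leaf {leaf_no}")
    for sub in subclusters:
        if sub.representative.name not in {m.name for m in sub.members}:
            raise ResolutionError(
                f"representative {sub.representative.name!r} not a member (leaf {leaf_no})"
            )


def aggregate_entity_records(
    triples: Sequence[RawTriple],
    definitions: Sequence | None,
    type_state: TypeResolutionState | None = None,
) -> list[EntityRecord]:
    """Collapse triple endpoints and defined names into one record per
    surface form, with mention counts, the majority resolved type and the
    concatenation of distinct definitions."""
    counts: Counter = Counter()
    types: dict[str, Counter] = {}
    defs: dict[str, list[str]] = {}
    for t in triples:
        for name, typ in ((t.source_name, t.source_type), (t.target_name, t.target_type)):
            counts[name] += 1
            resolved = type_state.resolve(typ) if type_state else typ
            types.setdefault(name, Counter())[resolved] += 1
    if definitions:
        for d in definitions:
            counts[d.name] += 0  # ensure presence even if never in a triple
            entry = defs.setdefault(d.name, [])
            if d.definition not in entry:
                entry.append(d.definition)
    records = []
    for name in sorted(counts):
        type_counter = types.get(name, Counter())
        best_type = (
            sorted(type_counter.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]
            if type_counter
            else ""
        )
        records.append(
            EntityRecord(
                name=name,
                type=best_type,
                definition=" ; ".join(defs.get(name, [])),
                count=counts[name],
            )
        )
    return records


def resolve_entities(
    records: Sequence[EntityRecord],
    embedder: EmbeddingBackend,
    resolver: ResolverBackend,
    cap: int = DEFAULT_CLUSTER_CAP,
    seed: int = 0,
) -> dict[str, str]:
    """Map each entity surface form to its sub-cluster representative.

    Embedding text is ``"name | type | definition"`` (missing definitions
    contribute an empty field), so identically defined variants embed
    close together even when the names differ, e.g. an abbreviation and
    its expansion.
    """
    if not records:
        raise ResolutionError("no entity records to resolve")
    texts = [f"{r.name} | {r.type} | {r.definition}" for r in records]
    return _cluster_and_map(records, texts, embedder, resolver, cap, seed)


def resolve_relations(
    triples: Sequence[RawTriple],
    embedder: EmbeddingBackend,
    resolver: ResolverBackend,
    type_state: TypeResolutionState | None = None,
    cap: int = DEFAULT_CLUSTER_CAP,
    seed: int = 0,
) -> dict[str, str]:
    """Cluster relation surfaces embedded in their dominant type context
    ``"<source type> <relation> <target type>"`` and map each to its
    representative."""
    if not triples:
        return {}
    counts: Counter = Counter(t.relation for t in triples)
    contexts: dict[str, Counter] = {}
    for t in triples:
        stype = type_state.resolve(t.source_type) if type_state else t.source_type
        ttype = type_state.resolve(t.target_type) if type_state else t.target_type
        contexts.setdefault(t.relation, Counter())[(stype, ttype)] += 1
    records, texts = [], []
    for rel in sorted(counts):
        (stype, ttype), _ = sorted(
            contexts[rel].items(), key=lambda kv: (-kv[1], kv[0])
        )[0]
        records.append(EntityRecord(name=rel, type="", definition="", count=counts[rel]))
        texts.append(f"{stype} {rel} {ttype}")
    return _cluster_and_map(records, texts, embedder, resolver, cap, seed)


# ---------------------------------------------------------------------------
# rule-based canonicalization


def _stem_verb(word: str) -> str:
    if word.endswith("ed"):
        word = word[:-2]
    elif word.endswith("s"):
        word = word[:-1]
    if word.endswith("e"):
        word = word[:-1]
    return word


def _relation_stem(relation: str) -> str:
    head, _, tail = relation.partition(" ")
    stem = _stem_verb(head)
    return f"{stem} {tail}".strip()


def _entity_stem(name: str) -> str:
    folded = name.casefold()
    if len(folded) > 3 and folded.endswith("s"):
        return folded[:-1]
    return folded


def synonym_collapse_map(counts: Counter, stem_fn, top_n: int) -> dict[str, str]:
    """Most-frequent-form rule: surfaces sharing a morphological stem
    collapse onto the most frequent member of their group (ties
    lexicographic), provided the group touches the top-N surfaces."""
    top = {s for s, _ in counts.most_common(top_n)}
    groups: dict[str, list[str]] = {}
    for surface in counts:
        groups.setdefault(stem_fn(surface), []).append(surface)
    out: dict[str, str] = {}
    for variants in groups.values():
        if len(variants) < 2 or not (set(variants) & top):
            continue
        best = sorted(variants, key=lambda s: (-counts[s], s))[0]
        for v in variants:
            if v != best:
                out[v] = best
    return out


@dataclass
class CanonicalizationResult:
    triples: list[RawTriple]
    #: inputs with source/target swapped where the passive rule fired, so
    #: index i of ``originals`` corresponds field-by-field to ``triples[i]``
    originals: list[RawTriple]
    log: list[tuple[str, str, str]]  # (rule id, before, after)
    entity_rewrites: dict[str, str]
    relation_rewrites: dict[str, str]


def canonicalize_rules(
    triples: Sequence[RawTriple], top_n: int = DEFAULT_TOP_N_RULES
) -> CanonicalizationResult:
    """Deterministic rewrite pass applied before embedding resolution.

    1. *case*: every surface group differing only by casing is rewritten
       to its most frequent casing (ties lexicographic);
    2. *passive*: passive relations are rewritten to their active form
       with source and target swapped; unlisted passive phrases pass
       through and are logged;
    3. *synonym*: among the ``top_n`` most frequent relation and entity
       surfaces, morphological variants (tense/number) collapse onto the
       most frequent member of their stem group.

    Every rewrite is logged with its rule id.
    """
    log: list[tuple[str, str, str]] = []

    # -- rule 1: canonical casing per fold group
    ent_counts = Counter()
    rel_counts = Counter()
    for t in triples:
        ent_counts[t.source_name] += 1
        ent_counts[t.target_name] += 1
        rel_counts[t.relation] += 1

    def casing_map(counts: Counter) -> dict[str, str]:
        groups: dict[str, list[str]] = {}
        for surface in counts:
            groups.setdefault(surface.casefold(), []).append(surface)
        out: dict[str, str] = {}
        for variants in groups.values():
            best = sorted(variants, key=lambda s: (-counts[s], s))[0]
            for v in variants:
                out[v] = best
        return out

    ent_case = casing_map(ent_counts)
    rel_case = casing_map(rel_counts)
    for before, after in list(ent_case.items()) + list(rel_case.items()):
        if before != after:
            log.append(("case", before, after))

    staged: list[RawTriple] = []
    originals: list[RawTriple] = []
    for t in triples:
        staged.append(
            replace(
                t,
                source_name=ent_case[t.source_name],
                target_name=ent_case[t.target_name],
                relation=rel_case[t.relation],
            )
        )
        originals.append(t)

    # -- rule 2: passive -> active with swap
    passive_cache: dict[str, str | None] = {}
    rewritten: list[RawTriple] = []
    swapped_originals: list[RawTriple] = []
    for t, orig in zip(staged, originals):
        rel = t.relation
        if rel not in passive_cache:
            active = None
            if grammar.PASSIVE_RELATION_RE.match(rel.casefold()):
                active = grammar.passive_to_active(rel.casefold())
                if active is None:
                    log.append(("passive_unmapped", rel, rel))
            passive_cache[rel] = active
        active = passive_cache[rel]
        if active is None:
            rewritten.append(t)
            swapped_originals.append(orig)
        else:
            log.append(("passive", rel, active))
            rewritten.append(
                replace(
                    t,
                    source_name=t.target_name,
                    source_type=t.target_type,
                    relation=active,
                    target_name=t.source_name,
                    target_type=t.source_type,
                )
            )
            swapped_originals.append(
                replace(
                    orig,
                    source_name=orig.target_name,
                    source_type=orig.target_type,
                    target_name=orig.source_name,
                    target_type=orig.source_type,
                )
            )

    # -- rule 3: most-frequent-form synonym collapsing over top-N surfaces
    rel_counts2 = Counter(t.relation for t in rewritten)
    ent_counts2 = Counter()
    for t in rewritten:
        ent_counts2[t.source_name] += 1
        ent_counts2[t.target_name] += 1

    rel_syn = synonym_collapse_map(rel_counts2, _relation_stem, top_n)
    ent_syn = synonym_collapse_map(ent_counts2, _entity_stem, top_n)
    for before, after in list(rel_syn.items()) + list(ent_syn.items()):
        log.append(("synonym", before, after))

    final = [
        replace(
            t,
            source_name=ent_syn.get(t.source_name, t.source_name),
            target_name=ent_syn.get(t.target_name, t.target_name),
            relation=rel_syn.get(t.relation, t.relation),
        )
        for t in rewritten
    ]

    # per-surface composition of the rewrites, for tracing originals
    entity_rewrites: dict[str, str] = {}
    for surface in ent_counts:
        cased = ent_case[surface]
        entity_rewrites[surface] = ent_syn.get(cased, cased)
    relation_rewrites: dict[str, str] = {}
    for surface in rel_counts:
        cased = rel_case[surface]
        active = grammar.passive_to_active(cased.casefold())
        if grammar.PASSIVE_RELATION_RE.match(cased.casefold()) and active is not None:
            cased = active
        relation_rewrites[surface] = rel_syn.get(cased, cased)

    return CanonicalizationResult(final, swapped_originals, log, entity_rewrites, relation_rewrites)


# ---------------------------------------------------------------------------
# resolution map and application


@dataclass
class ResolutionMap:
    """Total surface -> canonical maps for types, entities and relations,
    invertible back to the original surface forms."""

    type_map: dict[str, str] = field(default_factory=dict)
    entity_map: dict[str, str] = field(default_factory=dict)
    relation_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.type_map, self.entity_map, self.relation_map):
            for canonical in list(mapping.values()):
                mapping.setdefault(canonical, canonical)

    def surfaces_for(self, canonical: str, which: str = "entity") -> list[str]:
        mapping = getattr(self, f"{which}_map")
        return sorted(s for s, c in mapping.items() if c == canonical)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "type_map": self.type_map,
                    "entity_map": self.entity_map,
                    "relation_map": self.relation_map,
                },
                fh,
                indent=1,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "ResolutionMap":
        with open(path, encoding="utf-8") as fh:
            rec = json.load(fh)
        return cls(rec["type_map"], rec["entity_map"], rec["relation_map"])


@dataclass(frozen=True)
class ResolvedTriple:
    """A triple carrying both its original surface forms and the resolved
    canonical forms; provenance untouched."""

    source_name: str
    source_type: str
    relation: str
    target_name: str
    target_type: str
    provenance: str
    source_resolved: str
    source_type_resolved: str
    relation_resolved: str
    target_resolved: str
    target_type_resolved: str
    species: str | None = None
    evidence: str | None = None

    @property
    def resolved_key(self) -> tuple[str, str, str]:
        return (self.source_resolved, self.relation_resolved, self.target_resolved)


def _lookup(mapping: Mapping[str, str], surface: str, kind: str) -> str:
    try:
        return mapping[surface]
    except KeyError:
        raise ResolutionError(f"unmapped {kind} surface {surface!r}") from None


def apply_resolution(
    triples: Sequence[RawTriple],
    rmap: ResolutionMap,
    originals: Sequence[RawTriple] | None = None,
) -> list[ResolvedTriple]:
    """Rewrite triples through a resolution map, retaining original
    surface forms as metadata.

    ``originals`` (same length/order) supplies the pre-canonicalization
    surfaces to record; by default the input triples are their own
    originals.  Raises on any surface missing from the map.
    """
    if originals is None:
        originals = triples
    out: list[ResolvedTriple] = []
    for t, orig in zip(triples, originals):
        out.append(
            ResolvedTriple(
                source_name=orig.source_name,
                source_type=orig.source_type,
                relation=orig.relation,
                target_name=orig.target_name,
                target_type=orig.target_type,
                provenance=t.provenance,
                species=t.species,
                evidence=t.evidence,
                source_resolved=_lookup(rmap.entity_map, t.source_name, "entity"),
                source_type_resolved=rmap.type_map.get(t.source_type, t.source_type),
                relation_resolved=_lookup(rmap.relation_map, t.relation, "relation"),
                target_resolved=_lookup(rmap.entity_map, t.target_name, "entity"),
                target_type_resolved=rmap.type_map.get(t.target_type, t.target_type),
            )
        )
    return out


# ---------------------------------------------------------------------------
# full pipeline


@dataclass
class ResolutionResult:
    resolved_triples: list[ResolvedTriple]
    map: ResolutionMap
    rule_log: list[tuple[str, str, str]]
    type_state: TypeResolutionState
    #: canonical entity name -> definitions, for graph assembly
    definitions: dict[str, list[str]]

    def full_entity_map(self) -> dict[str, str]:
        """Composition of rule rewrites and embedding resolution: original
        extracted surface -> canonical entity."""
        return self._full_map

    def full_relation_map(self) -> dict[str, str]:
        return self._full_rel_map


def resolve_corpus(
    triples: Sequence[RawTriple],
    definitions: Sequence | None = None,
    embedder: EmbeddingBackend | None = None,
    resolver: ResolverBackend | None = None,
    cap: int = DEFAULT_CLUSTER_CAP,
    reference_size: int = DEFAULT_REFERENCE_SIZE,
    k_neighbors: int = DEFAULT_TYPE_NEIGHBORS,
    top_n_rules: int = DEFAULT_TOP_N_RULES,
    seed: int = 0,
) -> ResolutionResult:
    """Run canonicalization rules, then type, entity and relation
    resolution, and apply the combined map."""
    if not triples:
        raise ResolutionError("no triples to resolve")
    embedder = embedder or HashedNgramEmbedder()
    resolver = resolver or IdentityResolver()

    # case folding and passive repair run first; the frequency-driven
    # synonym rule runs *after* the embedding tiers, on the vocabulary the
    # resolver left unmerged — otherwise a frequent tense variant could
    # erase the canonical surface before the resolver ever sees it
    canon = canonicalize_rules(triples, top_n=0)

    type_freq: Counter = Counter()
    for t in canon.triples:
        type_freq[t.source_type] += 1
        type_freq[t.target_type] += 1
    type_state = resolve_types(
        type_freq, embedder, resolver, reference_size=reference_size, k_neighbors=k_neighbors
    )

    records = aggregate_entity_records(canon.triples, definitions, type_state)
    entity_map = resolve_entities(records, embedder, resolver, cap=cap, seed=seed)
    relation_map = resolve_relations(
        canon.triples, embedder, resolver, type_state, cap=cap, seed=_child_seed(seed, 7)
    )

    # rule 3 on the resolved vocabularies, mention-weighted
    ent_counts: Counter = Counter()
    rel_counts: Counter = Counter()
    for t in canon.triples:
        ent_counts[entity_map[t.source_name]] += 1
        ent_counts[entity_map[t.target_name]] += 1
        rel_counts[relation_map[t.relation]] += 1
    ent_syn = synonym_collapse_map(ent_counts, _entity_stem, top_n_rules)
    rel_syn = synonym_collapse_map(rel_counts, _relation_stem, top_n_rules)
    rule_log = list(canon.log)
    rule_log.extend(("synonym", b, a) for b, a in ent_syn.items())
    rule_log.extend(("synonym", b, a) for b, a in rel_syn.items())
    entity_map = {s: ent_syn.get(c, c) for s, c in entity_map.items()}
    relation_map = {s: rel_syn.get(c, c) for s, c in relation_map.items()}

    rmap = ResolutionMap(dict(type_state.mapping), entity_map, relation_map)
    resolved = apply_resolution(canon.triples, rmap, originals=canon.originals)

    defs_by_canonical: dict[str, list[str]] = {}
    if definitions:
        for d in definitions:
            rewritten = canon.entity_rewrites.get(d.name, d.name)
            canonical = entity_map.get(rewritten, rewritten)
            entry = defs_by_canonical.setdefault(canonical, [])
            if d.definition not in entry:
                entry.append(d.definition)

    result = ResolutionResult(resolved, rmap, rule_log, type_state, defs_by_canonical)
    result._full_map = {
        surface: entity_map.get(rew, rew) for surface, rew in canon.entity_rewrites.items()
    }
    for surface, canonical in entity_map.items():
        result._full_map.setdefault(surface, canonical)
    result._full_rel_map = {
        surface: relation_map.get(rew, rew)
        for surface, rew in canon.relation_rewrites.items()
    }
    for surface, canonical in relation_map.items():
        result._full_rel_map.setdefault(surface, canonical)
    return result
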