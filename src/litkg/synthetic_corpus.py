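"""Seeded generator of toy corpora with known ground truth.

Every downstream stage (extraction, resolution, graph assembly, analytics)
is testable offline against corpora produced here: canonical entities are
rendered with surface variation (casing, pluralization, abbreviation),
relations appear in active or passive voice, and the generator returns the
exact surface-form clusters and canonical triples it planted.

Entities follow two naming conventions seen in plant literature: AGI locus
identifiers (``AT1G01010``) and descriptive alias names (``heat factor``)
that additionally carry an upper-case abbreviation (``HF7``).  Each surface
form is introduced by a glossary sentence (``X is defined as ...``) the
first time it appears in an article, so entity definitions — which the
resolution stage embeds alongside names — are recoverable from the text.

Passive sentences invert the surface order of the two entities but *not*
the ground-truth direction, planting exactly the hazard the passive-to-
active canonicalization rule must repair.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import grammar
from .corpus_io import Document, Section, make_provenance_key
from .kg_analytics import GraphStats


class SyntheticSpecError(ValueError):
    pass


@dataclass
class CorpusSpec:
    """Study conditions for one synthetic corpus.

    Defaults are the reference conditions used throughout the test suite:
    100 articles over 200 canonical entities with moderate surface
    variation (30% casing, 30% pluralization, 20% abbreviation) and 30%
    passive-voice sentences.
    """

    n_articles: int = 100
    n_canonical_entities: int = 200
    n_canonical_relations: int = 6
    variant_rates: dict[str, float] = field(
        default_factory=lambda: {"casing": 0.3, "plural": 0.3, "abbreviation": 0.2}
    )
    passive_rate: float = 0.3
    sections_per_article: dict[str, float] = field(
        default_factory=lambda: {"abstract": 1.0, "intro": 0.35, "results": 0.35, "discuss": 0.3}
    )
    triples_per_section: tuple[int, int] = (2, 4)
    seed: int = 7

    def validate(self) -> None:
        probs = [self.passive_rate, *self.variant_rates.values(), *self.sections_per_article.values()]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise SyntheticSpecError("all probabilities must lie in [0, 1]")
        if self.n_articles <= 0 or self.n_canonical_relations <= 0:
            raise SyntheticSpecError("counts must be positive")
        if self.n_canonical_relations > len(grammar.RELATION_FAMILIES):
            raise SyntheticSpecError(
                f"at most {len(grammar.RELATION_FAMILIES)} relation families available"
            )
        lo, hi = self.triples_per_section
        if lo < 0 or hi < lo:
            raise SyntheticSpecError("triples_per_section must be a (min, max) range")
        if self.n_canonical_entities < 2 and hi > 0:
            raise SyntheticSpecError("need at least 2 canonical entities to emit triples")
        n_alias = self.n_canonical_entities - self.n_canonical_entities // 2
        if n_alias > len(grammar.ALIAS_ADJECTIVES) * len(grammar.ALIAS_NOUNS):
            raise SyntheticSpecError("alias vocabulary exhausted; reduce n_canonical_entities")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "n_articles": self.n_articles,
                    "n_canonical_entities": self.n_canonical_entities,
                    "n_canonical_relations": self.n_canonical_relations,
                    "variant_rates": self.variant_rates,
                    "passive_rate": self.passive_rate,
                    "sections_per_article": self.sections_per_article,
                    "triples_per_section": list(self.triples_per_section),
                    "seed": self.seed,
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CorpusSpec":
        with open(path, encoding="utf-8") as fh:
            rec = json.load(fh)
        if "triples_per_section" in rec:
            rec["triples_per_section"] = tuple(rec["triples_per_section"])
        return cls(**rec)


@dataclass
class GroundTruth:
    """Answer key for one generated corpus.

    ``entity_clusters`` and ``relation_clusters`` map every emitted surface
    form to its canonical form; ``canonical_triples`` maps each canonical
    (source, relation, target) statement to the provenance keys of the
    sentences asserting it.
    """

    entity_clusters: dict[str, str] = field(default_factory=dict)
    relation_clusters: dict[str, str] = field(default_factory=dict)
    canonical_triples: dict[tuple[str, str, str], list[str]] = field(default_factory=dict)
    entity_types: dict[str, str] = field(default_factory=dict)
    definitions: dict[str, str] = field(default_factory=dict)

    def entity_labels(self, surfaces: list[str]) -> list[str]:
        """Cluster label (canonical entity) per surface form, for ARI scoring."""
        return [self.entity_clusters[s] for s in surfaces]

    def to_json(self, path: str | Path) -> None:
        rec = {
            "entity_clusters": self.entity_clusters,
            "relation_clusters": self.relation_clusters,
            "canonical_triples": {
                "\t".join(k): v for k, v in self.canonical_triples.items()
            },
            "entity_types": self.entity_types,
            "definitions": self.definitions,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rec, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            rec = json.load(fh)
        return cls(
            entity_clusters=rec["entity_clusters"],
            relation_clusters=rec["relation_clusters"],
            canonical_triples={
                tuple(k.split("\t")): v for k, v in rec["canonical_triples"].items()
            },
            entity_types=rec["entity_types"],
            definitions=rec["definitions"],
        )


@dataclass(frozen=True)
class _Entity:
    canonical: str
    kind: str  # "agi" | "alias"
    abbrev: str | None
    definition: str
    type: str


def _build_entities(spec: CorpusSpec, rng: np.random.Generator) -> list[_Entity]:
    n_agi = spec.n_canonical_entities // 2
    n_alias = spec.n_canonical_entities - n_agi
    entities: list[_Entity] = []

    nums = rng.choice(np.arange(1, 100000), size=n_agi, replace=False)
    for i in range(n_agi):
        chrom = int(rng.integers(1, 6))
        agi = f"AT{chrom}G{int(nums[i]):05d}"
        noun = grammar.ALIAS_NOUNS[int(rng.integers(len(grammar.ALIAS_NOUNS)))]
        process = grammar.PROCESSES[int(rng.integers(len(grammar.PROCESSES)))]
        definition = f"gene locus {agi} encoding a {noun} involved in {process}"
        entities.append(_Entity(agi, "agi", None, definition, "gene identifier"))

    combos = list(itertools.product(grammar.ALIAS_ADJECTIVES, grammar.ALIAS_NOUNS))
    picks = rng.choice(len(combos), size=n_alias, replace=False)
    for j, pick in enumerate(picks):
        adj, noun = combos[int(pick)]
        name = f"{adj} {noun}"
        abbrev = f"{adj[0].upper()}{noun[0].upper()}{j}"
        process = grammar.PROCESSES[int(rng.integers(len(grammar.PROCESSES)))]
        definition = f"the {adj} {noun} protein {j} required for {process} in thale cress"
        entities.append(_Entity(name, "alias", abbrev, definition, "gene"))
    return entities


def _render_surface(ent: _Entity, spec: CorpusSpec, rng: np.random.Generator) -> str:
    """Draw one surface form.  All random draws are consumed unconditionally
    so that raising one variant rate never changes which other draws fire
    (surface vocabulary grows monotonically in each rate)."""
    r_abbr = rng.random()
    r_case = rng.random()
    case_style = int(rng.integers(2))
    r_plural = rng.random()

    rates = spec.variant_rates
    if ent.kind == "alias" and r_abbr < rates.get("abbreviation", 0.0):
        return ent.abbrev  # fixed spelling; no further variation
    name = ent.canonical
    if r_case < rates.get("casing", 0.0):
        if ent.kind == "agi":
            # AT1G01010 -> At1g01010 or at1g01010
            mixed = name[0] + name[1].lower() + name[2] + name[3].lower() + name[4:]
            name = mixed if case_style == 0 else name.lower()
        else:
            name = name.title() if case_style == 0 else name.upper()
    if r_plural < rates.get("plural", 0.0):
        name = name + "s"
    return name


def _pick_relation_variant(fam: grammar.RelationFamily, rng: np.random.Generator) -> str:
    r = rng.random()
    if r < grammar.CANONICAL_VARIANT_WEIGHT or len(fam.variants) == 1:
        return fam.variants[0]
    rest = fam.variants[1:]
    return rest[int(rng.integers(len(rest)))]


_JOURNALS = (
    "Plant Physiology", "The Plant Journal", "Plant Cell",
    "Frontiers in Plant Science", "New Phytologist", "BMC Plant Biology",
    "PLOS One", "Scientific Reports",
)


def generate_corpus(spec: CorpusSpec) -> tuple[list[Document], GroundTruth]:
    """Generate a corpus and its answer key.  Deterministic per seed."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    entities = _build_entities(spec, rng)
    families = grammar.RELATION_FAMILIES[: spec.n_canonical_relations]

    truth = GroundTruth()
    for ent in entities:
        truth.entity_types[ent.canonical] = ent.type
        truth.definitions[ent.canonical] = ent.definition
    for fam in families:
        for v in fam.variants:
            truth.relation_clusters[v] = fam.canonical
        if fam.passive:
            truth.relation_clusters[fam.passive] = fam.canonical

    docs: list[Document] = []
    lo, hi = spec.triples_per_section
    for a in range(spec.n_articles):
        pmid = str(10_000_000 + a)
        journal = _JOURNALS[int(rng.integers(len(_JOURNALS)))]
        year = 2010 + int(rng.integers(15))
        surfaces_seen: set[str] = set()
        entities_seen: set[str] = set()
        sections: list[Section] = []
        included = [
            label
            for label in ("abstract", "intro", "results", "discuss")
            if rng.random() < spec.sections_per_article.get(label, 0.0)
        ]
        if not included:
            included = ["abstract"]
        for label in included:
            prov = make_provenance_key(pmid, label)
            glossary: list[str] = []
            statements: list[str] = []
            n_triples = int(rng.integers(lo, hi + 1)) if hi > 0 else 0
            for _ in range(n_triples):
                i, j = rng.choice(len(entities), size=2, replace=False)
                src, tgt = entities[int(i)], entities[int(j)]
                fam = families[int(rng.integers(len(families)))]
                rel_surface = _pick_relation_variant(fam, rng)
                r_passive = rng.random()
                organ = grammar.ORGANS[int(rng.integers(len(grammar.ORGANS)))]
                src_surface = _render_surface(src, spec, rng)
                tgt_surface = _render_surface(tgt, spec, rng)

                for ent, surface in ((src, src_surface), (tgt, tgt_surface)):
                    truth.entity_clusters[surface] = ent.canonical
                    if ent.canonical not in entities_seen:
                        entities_seen.add(ent.canonical)
                        truth.entity_clusters[ent.canonical] = ent.canonical
                        surfaces_seen.add(ent.canonical)
                        glossary.append(
                            f"{ent.canonical} {grammar.DEFINITION_CONNECTIVE} {ent.definition}."
                        )
                    if surface not in surfaces_seen:
                        surfaces_seen.add(surface)
                        glossary.append(
                            f"{surface} {grammar.DEFINITION_CONNECTIVE} {ent.definition}."
                        )

                use_passive = fam.passive is not None and r_passive < spec.passive_rate
                if use_passive:
                    statements.append(f"{tgt_surface} {fam.passive} {src_surface}.")
                else:
                    statements.append(f"{src_surface} {rel_surface} {tgt_surface} in {organ}.")
                key = (src.canonical, fam.canonical, tgt.canonical)
                truth.canonical_triples.setdefault(key, []).append(prov)
            sections.append(Section(label=label, text=" ".join(glossary + statements)))
        docs.append(
            Document(pmid=pmid, title=f"Synthetic study {a}", journal=journal,
                     year=year, sections=sections)
        )
    return docs, truth


def corpus_answer_key(truth: GroundTruth) -> GraphStats:
    """Expected graph-level counts after perfect resolution."""
    endpoints = {e for (s, _, t) in truth.canonical_triples for e in (s, t)}
    relations = {r for (_, r, _) in truth.canonical_triples}
    pairs = {(e, truth.entity_types[e]) for e in endpoints}
    types = {truth.entity_types[e] for e in endpoints}
    return GraphStats(
        n_entities=len(endpoints),
        n_entity_type_pairs=len(pairs),
        n_relation_types=len(relations),
        n_entity_types=len(types),
        n_unique_triples=len(truth.canonical_triples),
    )
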