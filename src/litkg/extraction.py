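"""Turn document sections into raw triples and entity definitions.

Extraction is delegated to a pluggable :class:`ExtractorBackend`.  The
deterministic :class:`TemplateExtractor` shipped here inverts the synthetic
template grammar exactly and is the backend used by all tests; a live LLM
backend can be plugged in behind the same contract without touching the
rest of the pipeline.  Passive sentences are recorded verbatim in surface
order — direction is repaired later by rule-based canonicalization.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from . import grammar
from .corpus_io import Document, iter_section_chunks

logger = logging.getLogger(__name__)

#: Prompt templates for a live LLM backend, recorded as opaque
#: configuration.  Content deliberately untested.
PROMPT_TEMPLATES = {
    "triples": (
        "Extract all (entity, relationship, entity) statements from the text "
        "below, with an entity type for each entity and, when stated, the "
        "species and experimental evidence. Text:\n{text}"
    ),
    "definitions": "List each entity defined in the text with its definition. Text:\n{text}",
}

TRIPLE_COLUMNS = (
    "source_name", "source_type", "relation", "target_name", "target_type",
    "provenance", "species", "evidence",
)


@dataclass(frozen=True)
class RawTriple:
    """One extracted statement, all fields verbatim surface text."""

    source_name: str
    source_type: str
    relation: str
    target_name: str
    target_type: str
    provenance: str
    species: str | None = None
    evidence: str | None = None

    def __post_init__(self) -> None:
        if not (self.source_name and self.target_name and self.relation):
            raise ValueError("triple names and relation must be non-empty")
        if not self.provenance:
            raise ValueError("triple must carry a provenance key")


@dataclass(frozen=True)
class EntityDefinition:
    name: str
    definition: str
    provenance: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("definition name must be non-empty")


class ExtractorBackend(Protocol):
    def extract(
        self, text: str, provenance: str
    ) -> tuple[list[RawTriple], list[EntityDefinition]]: ...


class TemplateExtractor:
    """Mock backend bound to the synthetic template grammar.

    A pure function of its inputs: parses active sentences
    ``A <rel> B in <organ>.``, passive sentences ``B <passive> A.`` and
    glossary sentences ``X is defined as D.``.  Entity types are assigned
    at extraction time by pattern (AGI identifiers -> "gene identifier",
    template organs -> "organ", otherwise "gene").
    """

    def __init__(self) -> None:
        rel_alt = "|".join(re.escape(s) for s in grammar.active_relation_surfaces())
        organ_alt = "|".join(grammar.ORGANS)
        self._active_re = re.compile(
            rf"^(?P<a>.+?) (?P<rel>{rel_alt}) (?P<b>.+?)(?: in (?P<organ>{organ_alt}))?\.$"
        )
        self._passive_re = re.compile(
            r"^(?P<b>.+?) (?P<rel>(?:is|are|was|were) \w+ by) (?P<a>.+?)\.$"
        )
        self._definition_re = re.compile(
            rf"^(?P<name>.+?) {grammar.DEFINITION_CONNECTIVE} (?P<def>.+)\.$"
        )

    def extract(
        self, text: str, provenance: str
    ) -> tuple[list[RawTriple], list[EntityDefinition]]:
        triples: list[RawTriple] = []
        definitions: list[EntityDefinition] = []
        for sentence in re.split(r"(?<=\.)\s+", text.strip()):
            if not sentence:
                continue
            m = self._definition_re.match(sentence)
            if m:
                definitions.append(
                    EntityDefinition(m.group("name"), m.group("def"), provenance)
                )
                continue
            m = self._passive_re.match(sentence)
            if m:
                # surface order kept: source is the grammatical subject
                triples.append(
                    RawTriple(
                        source_name=m.group("b"),
                        source_type=grammar.classify_entity_type(m.group("b")),
                        relation=m.group("rel"),
                        target_name=m.group("a"),
                        target_type=grammar.classify_entity_type(m.group("a")),
                        provenance=provenance,
                    )
                )
                continue
            m = self._active_re.match(sentence)
            if m:
                triples.append(
                    RawTriple(
                        source_name=m.group("a"),
                        source_type=grammar.classify_entity_type(m.group("a")),
                        relation=m.group("rel"),
                        target_name=m.group("b"),
                        target_type=grammar.classify_entity_type(m.group("b")),
                        provenance=provenance,
                    )
                )
        return triples, definitions


@dataclass
class ExtractionResult:
    triples: list[RawTriple] = field(default_factory=list)
    definitions: list[EntityDefinition] = field(default_factory=list)
    errors: list[tuple[str, str]] = field(default_factory=list)  # (provenance, message)


def extract_document(doc: Document, backend: ExtractorBackend) -> ExtractionResult:
    """One backend call per section chunk, in section order.

    A backend failure on one section is recorded and the remaining
    sections are still processed.
    """
    result = ExtractionResult()
    for key, section in iter_section_chunks(doc):
        if not section.text:
            continue
        try:
            triples, definitions = backend.extract(section.text, str(key))
        except Exception as exc:
            logger.warning("extraction failed for %s: %s", key, exc)
            result.errors.append((str(key), str(exc)))
            continue
        result.triples.extend(triples)
        result.definitions.extend(definitions)
    return result


def extract_corpus(
    corpus: Sequence[Document],
    backend: ExtractorBackend,
    batch_size: int = 50,
    done_pmids: set[str] | None = None,
) -> ExtractionResult:
    """Concatenate per-document outputs over the corpus.

    ``done_pmids`` allows resuming an interrupted run by pmid; documents
    already processed are skipped.  ``batch_size`` only controls progress
    logging granularity for the deterministic backends.
    """
    result = ExtractionResult()
    done_pmids = done_pmids or set()
    for i, doc in enumerate(corpus):
        if doc.pmid in done_pmids:
            continue
        part = extract_document(doc, backend)
        result.triples.extend(part.triples)
        result.definitions.extend(part.definitions)
        result.errors.extend(part.errors)
        if batch_size and (i + 1) % batch_size == 0:
            logger.info("extracted %d/%d documents", i + 1, len(corpus))
    return result


# ---------------------------------------------------------------------------
# TSV round-trip with tab/newline escaping


def _escape(value: str | None) -> str:
    if value is None:
        return ""
    return value.replace("\\", "\\\\").replace("\t", "\\t").replace("\n", "\\n")


def _unescape(value: str) -> str:
    out: list[str] = []
    i = 0
    while i < len(value):
        ch = value[i]
        if ch == "\\" and i + 1 < len(value):
            nxt = value[i + 1]
            out.append({"t": "\t", "n": "\n", "\\": "\\"}.get(nxt, nxt))
            i += 2
        else:
            out.append(ch)
            i += 1
    return "".join(out)


def save_triples(triples: Iterable[RawTriple], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(TRIPLE_COLUMNS) + "\n")
        for t in triples:
            row = [
                _escape(getattr(t, col)) for col in TRIPLE_COLUMNS
            ]
            fh.write("\t".join(row) + "\n")


def load_triples(path: str | Path) -> list[RawTriple]:
    triples: list[RawTriple] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != TRIPLE_COLUMNS:
            raise ValueError(f"unexpected triple table header: {header}")
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(TRIPLE_COLUMNS):
                raise ValueError(f"malformed triple row at line {lineno}")
            values = [_unescape(f) for f in fields]
            rec = dict(zip(TRIPLE_COLUMNS, values))
            rec["species"] = rec["species"] or None
            rec["evidence"] = rec["evidence"] or None
            triples.append(RawTriple(**rec))
    return triples
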