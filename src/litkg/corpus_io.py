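"""Data model and JSONL I/O for section-structured article corpora.

A corpus is an ordered collection of :class:`Document` objects, each holding
a PubMed identifier, bibliographic metadata and a list of labeled
:class:`Section` chunks (abstract, intro, results, discuss, other).  Every
extracted statement is tied back to its source chunk through a provenance
key of the form ``<pmid>_<label><ordinal>``, e.g. ``37008510_intro`` or
``24009617_intro3`` for the third chunk of a long introduction.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

SECTION_LABELS: tuple[str, ...] = ("abstract", "intro", "results", "discuss", "other")

#: NCBI E-utilities query template used to assemble an Arabidopsis-centric
#: corpus.  Shipped as configuration only; this package never downloads.
NCBI_QUERY_TEMPLATE = (
    "(Arabidopsis thaliana[Title/Abstract] AND {query_term}[tw]) OR "
    "(Arabidopsis[Title/Abstract] AND {query_term}[tw]) OR "
    "(Thale cress[Title/Abstract] AND {query_term}[tw]) OR "
    "(Mouse ear cress[Title/Abstract] AND {query_term}[tw]) OR "
    "(Mouse-ear cress[Title/Abstract] AND {query_term}[tw])"
)

_KEY_RE = re.compile(r"^(?P<pmid>\d+)_(?P<label>[a-z]+?)(?P<ordinal>\d*)$")


class CorpusError(ValueError):
    """Malformed corpus content (bad line, duplicate pmid, bad label)."""


@dataclass(frozen=True)
class ProvenanceKey:
    """Identifies the text chunk a statement came from.

    ``ordinal`` 0 means the section was a single chunk and serializes
    without a suffix; ordinal ``n >= 1`` serializes as ``intro3`` style.
    """

    pmid: str
    label: str
    ordinal: int = 0

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise CorpusError(f"pmid must be a non-empty digit string, got {self.pmid!r}")
        if self.label not in SECTION_LABELS:
            raise CorpusError(f"unknown section label {self.label!r}")
        if self.ordinal < 0:
            raise CorpusError("ordinal must be >= 0")

    def __str__(self) -> str:
        suffix = str(self.ordinal) if self.ordinal else ""
        return f"{self.pmid}_{self.label}{suffix}"


def make_provenance_key(pmid: str, section_label: str, ordinal: int = 0) -> str:
    """Serialize a provenance key, e.g. ``("37008510", "intro")`` -> ``"37008510_intro"``."""
    return str(ProvenanceKey(pmid, section_label, ordinal))


def parse_provenance_key(key: str) -> ProvenanceKey:
    """Parse ``"24009617_intro3"`` -> ``ProvenanceKey("24009617", "intro", 3)``.

    Round-trips losslessly with :func:`make_provenance_key`.
    """
    m = _KEY_RE.match(key)
    if m is None:
        raise CorpusError(f"malformed provenance key {key!r}")
    label = m.group("label")
    if label not in SECTION_LABELS:
        raise CorpusError(f"unknown section label {label!r} in key {key!r}")
    ordinal = int(m.group("ordinal")) if m.group("ordinal") else 0
    return ProvenanceKey(m.group("pmid"), label, ordinal)


@dataclass
class Section:
    """One labeled text chunk of an article.  ``text`` may be empty."""

    label: str
    text: str = ""
    ordinal: int = 0

    def __post_init__(self) -> None:
        if self.label not in SECTION_LABELS:
            raise CorpusError(f"unknown section label {self.label!r}")


@dataclass
class Document:
    """One article: pmid, bibliographic metadata and ordered sections.

    ``authors`` is optional metadata required only by author-mode search.
    """

    pmid: str
    title: str = ""
    journal: str = ""
    year: int = 0
    sections: list[Section] = field(default_factory=list)
    authors: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.pmid or not self.pmid.isdigit():
            raise CorpusError(f"pmid must be a non-empty digit string, got {self.pmid!r}")
        seen: set[tuple[str, int]] = set()
        for sec in self.sections:
            key = (sec.label, sec.ordinal)
            if key in seen:
                raise CorpusError(
                    f"document {self.pmid}: duplicate section {sec.label!r} ordinal {sec.ordinal}"
                )
            seen.add(key)

    def section(self, label: str, ordinal: int = 0) -> Section | None:
        for sec in self.sections:
            if sec.label == label and sec.ordinal == ordinal:
                return sec
        return None

    @property
    def text(self) -> str:
        return " ".join(sec.text for sec in self.sections if sec.text)

    def to_record(self) -> dict:
        rec = {
            "pmid": self.pmid,
            "title": self.title,
            "journal": self.journal,
            "year": self.year,
            "sections": [
                {"label": s.label, "ordinal": s.ordinal, "text": s.text}
                for s in self.sections
            ],
        }
        if self.authors is not None:
            rec["authors"] = list(self.authors)
        return rec

    @classmethod
    def from_record(cls, rec: dict) -> "Document":
        sections = [
            Section(
                label=s["label"],
                text=s.get("text", ""),
                ordinal=int(s.get("ordinal", 0)),
            )
            for s in rec.get("sections", [])
        ]
        return cls(
            pmid=str(rec["pmid"]),
            title=rec.get("title", ""),
            journal=rec.get("journal", ""),
            year=int(rec.get("year", 0)),
            sections=sections,
            authors=list(rec["authors"]) if "authors" in rec else None,
        )


def read_corpus(path: str | Path) -> list[Document]:
    """Read a JSONL corpus (one document per line, UTF-8).

    Raises :class:`CorpusError` naming the offending line on malformed
    JSON/records and naming the pmid on duplicates.
    """
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
                doc = Document.from_record(rec)
            except CorpusError:
                raise
            except Exception as exc:  # json or schema failure
                raise CorpusError(f"malformed corpus line {lineno}: {exc}") from exc
            if doc.pmid in seen:
                raise CorpusError(f"duplicate pmid {doc.pmid}")
            seen.add(doc.pmid)
            docs.append(doc)
    return docs


def write_corpus(corpus: Iterable[Document], path: str | Path) -> None:
    """Write documents as JSONL with deterministic key order."""
    with open(path, "w", encoding="utf-8") as fh:
        for doc in corpus:
            fh.write(json.dumps(doc.to_record(), sort_keys=True, ensure_ascii=False))
            fh.write("\n")


def iter_section_chunks(doc: Document) -> Iterator[tuple[ProvenanceKey, Section]]:
    """Yield (provenance key, section) pairs in document order."""
    for sec in doc.sections:
        yield ProvenanceKey(doc.pmid, sec.label, sec.ordinal), sec


def corpus_stats(corpus: Sequence[Document]) -> dict:
    """Summary counts used by ``litkg corpus stats``."""
    n_sections: dict[str, int] = {label: 0 for label in SECTION_LABELS}
    abstract_only = 0
    for doc in corpus:
        labels = {s.label for s in doc.sections}
        for s in doc.sections:
            n_sections[s.label] += 1
        if labels <= {"abstract"}:
            abstract_only += 1
    return {
        "n_documents": len(corpus),
        "n_abstract_only": abstract_only,
        "sections": n_sections,
        "journals": sorted({d.journal for d in corpus if d.journal}),
    }
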