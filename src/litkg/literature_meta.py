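"""Keyword-dictionary meta-analysis of article corpora.

Quantifies what a corpus is about before any graph is built: occurrence
counts of topic keywords in abstracts, journal-by-topic heat-map
matrices, keyword co-occurrence networks, method-diversity scores per
journal, and per-section yield statistics of the extraction stage.

Keyword matching is case-insensitive, word-boundary and phrase-aware; no
stemming is applied — dictionaries list the variants explicitly.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus_io import Document, parse_provenance_key

#: Default topic dictionaries (category -> topic -> keywords).  The lists
#: are deliberately small, plant-centric starting points; users supply
#: their own JSON for real studies.
DEFAULT_KEYWORDS: dict[str, dict[str, list[str]]] = {
    "organs": {
        "roots": ["root", "hair", "nodule", "mycorrhizae"],
        "leaves": ["leaf", "leaves", "mesophyll"],
        "flowers": ["flower", "petal", "stamen", "pollen"],
        "seeds": ["seed", "embryo", "endosperm"],
    },
    "processes": {
        "photosynthesis": ["photosynthesis", "photorespiration", "photosystem"],
        "external stimuli response": ["stress", "drought", "salt", "pathogen"],
        "rna biosynthesis": ["transcription", "promoter", "transcription factor"],
        "reproduction": ["flowering", "pollination", "fertilization"],
        "phytohormone action": ["auxin", "cytokinin", "abscisic acid", "jasmonic acid"],
    },
    "compartments": {
        "nucleus": ["nucleus", "nucleolus", "chromosome", "nuclear pore"],
        "membranes": ["membrane", "plasma membrane", "tonoplast"],
        "chloroplast": ["chloroplast", "thylakoid", "stroma"],
    },
}

#: Method categories for the diversity score.
DEFAULT_METHODS: dict[str, list[str]] = {
    "bioinformatics": ["sequence", "phylogenetic", "genomic", "alignment",
                       "differential expression"],
    "literature": ["previous studies", "reported", "reviewed", "known"],
    "advanced wet": ["pull-down", "transgenic", "yeast two-hybrid", "immunoblot"],
    "high throughput": ["rna-seq", "proteomics", "microarray", "mass spectrometry"],
}

#: Embedding parameters recorded for the downstream 2-D visualization
#: (delegated to a library t-SNE implementation).
TSNE_PARAMS = {"perplexity": 40, "n_iter": 1000}


class KeywordError(ValueError):
    pass


def load_keyword_dictionary(path: str | Path) -> dict[str, dict[str, list[str]]]:
    with open(path, encoding="utf-8") as fh:
        dictionary = json.load(fh)
    validate_keyword_dictionary(dictionary)
    return dictionary


def validate_keyword_dictionary(dictionary: Mapping) -> None:
    for category, topics in dictionary.items():
        if not topics:
            raise KeywordError(f"category {category!r} has no topics")
        for topic, keywords in topics.items():
            if not keywords:
                raise KeywordError(f"topic {category}/{topic} has an empty keyword list")


def _keyword_re(keyword: str) -> re.Pattern:
    # word-boundary phrase match: "root" must not match inside "rooting"
    return re.compile(rf"\b{re.escape(keyword.casefold())}\b")


def count_keywords(
    doc: Document | str,
    topics: Mapping[str, Sequence[str]],
    section: str = "abstract",
) -> dict[str, int]:
    """Occurrence counts per topic in one abstract (or a raw text).

    Counts occurrences, not presence: "root root hair" scores 3 against
    ``roots = [root, hair]``.
    """
    if isinstance(doc, Document):
        sec = doc.section(section)
        text = sec.text if sec else ""
    else:
        text = doc
    folded = text.casefold()
    return {
        topic: sum(len(_keyword_re(kw).findall(folded)) for kw in keywords)
        for topic, keywords in topics.items()
    }


def topic_count_matrix(
    corpus: Sequence[Document],
    topics: Mapping[str, Sequence[str]],
    section: str = "abstract",
) -> pd.DataFrame:
    """Articles x topics occurrence-count matrix (index = pmid)."""
    rows = {doc.pmid: count_keywords(doc, topics, section) for doc in corpus}
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(topics)).fillna(0).astype(int)


def abstracts_containing(counts: pd.DataFrame) -> pd.Series:
    """Number of abstracts containing each topic at least once (an
    abstract can contain multiple keywords and count toward several
    topics)."""
    return (counts > 0).sum(axis=0)


def journal_topic_matrix(
    counts: pd.DataFrame, journals: Sequence[str]
) -> tuple[pd.DataFrame, list[str]]:
    """Per-journal topic sums normalized by the journal's row maximum.

    Every nonzero row attains 1.  All-zero rows are left as zeros and
    returned in the flagged list.
    """
    if len(journals) != len(counts):
        raise KeywordError("one journal label per article row required")
    sums = counts.groupby(pd.Index(journals, name="journal")).sum()
    flagged: list[str] = []
    normalized = sums.astype(float).copy()
    for journal, row in sums.iterrows():
        m = row.max()
        if m == 0:
            flagged.append(journal)
        else:
            normalized.loc[journal] = row / m
    return normalized, flagged


def cooccurrence_network(counts: pd.DataFrame, min_abstracts: int = 600):
    """Weighted keyword graph: nodes are topics, edge weight is the number
    of abstracts where both topics occur; edges below the threshold are
    dropped."""
    import networkx as nx

    g = nx.Graph()
    topics = list(counts.columns)
    g.add_nodes_from(topics)
    present = counts > 0
    for i, a in enumerate(topics):
        for b in topics[i + 1 :]:
            weight = int((present[a] & present[b]).sum())
            if weight >= min_abstracts:
                g.add_edge(a, b, weight=weight)
    return g


def method_diversity(
    doc: Document, methods: Mapping[str, Sequence[str]] = DEFAULT_METHODS
) -> dict[str, float]:
    """Per-category fraction of that category's method keywords present
    anywhere in the document: 1.0 means every method type under the
    category is used, 0.0 means none."""
    folded = doc.text.casefold()
    scores: dict[str, float] = {}
    for category, keywords in methods.items():
        if not keywords:
            raise KeywordError(f"empty method category {category!r}")
        present = sum(1 for kw in keywords if _keyword_re(kw).search(folded))
        scores[category] = present / len(keywords)
    return scores


def journal_method_diversity(
    corpus: Sequence[Document], methods: Mapping[str, Sequence[str]] = DEFAULT_METHODS
) -> pd.DataFrame:
    """Mean per-category diversity score per journal."""
    rows = []
    for doc in corpus:
        scores = method_diversity(doc, methods)
        scores["journal"] = doc.journal
        rows.append(scores)
    frame = pd.DataFrame(rows)
    return frame.groupby("journal").mean()


@dataclass
class SectionYieldStats:
    """Distribution of per-document yields for one section label, with
    Tukey outlier bounds Q1 - 1.5 IQR and Q3 + 1.5 IQR (quartiles by
    linear interpolation)."""

    median: float
    q1: float
    q3: float
    lower: float
    upper: float
    values: list[float]  # non-outlier values only
    n_total: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "SectionYieldStats":
        arr = np.asarray(values, dtype=float)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        iqr = q3 - q1
        lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        kept = arr[(arr >= lower) & (arr <= upper)]
        return cls(float(med), float(q1), float(q3), float(lower), float(upper),
                   kept.tolist(), len(arr))


def section_yield(triples: Sequence) -> dict[str, dict[str, SectionYieldStats]]:
    """Per-section-label distributions of relationships and unique
    entities extracted per document.

    Returns ``{label: {"relationships": stats, "entities": stats}}``;
    section labels with no triples are absent.
    """
    rels: dict[tuple[str, str], int] = {}
    ents: dict[tuple[str, str], set] = {}
    for t in triples:
        key = parse_provenance_key(t.provenance)
        doc_sec = (key.pmid, key.label)
        rels[doc_sec] = rels.get(doc_sec, 0) + 1
        ents.setdefault(doc_sec, set()).update((t.source_name, t.target_name))
    out: dict[str, dict[str, SectionYieldStats]] = {}
    labels = {label for (_, label) in rels}
    for label in sorted(labels):
        rel_values = [n for (pmid, lab), n in rels.items() if lab == label]
        ent_values = [len(s) for (pmid, lab), s in ents.items() if lab == label]
        out[label] = {
            "relationships": SectionYieldStats.from_values(rel_values),
            "entities": SectionYieldStats.from_values(ent_values),
        }
    return out


def topic_matrix_for_embedding(counts: pd.DataFrame) -> tuple[np.ndarray, dict]:
    """Numeric article x topic matrix plus the recorded embedding
    parameters, ready to forward to a library t-SNE implementation."""
    return counts.to_numpy(dtype=float), dict(TSNE_PARAMS)
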