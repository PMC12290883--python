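"""Shared fixtures: small synthetic corpora and pre-run pipeline stages."""

from __future__ import annotations

import pytest

from litkg import extraction, resolution, synthetic_corpus
from litkg.extraction import RawTriple
from litkg.resolution import ResolvedTriple


def make_raw(src, rel, tgt, prov="1_abstract", stype="gene", ttype="gene", **kw):
    return RawTriple(src, stype, rel, tgt, ttype, prov, **kw)


def make_resolved(src, rel, tgt, prov="1_abstract", stype="gene", ttype="gene",
                  rsrc=None, rrel=None, rtgt=None, rstype=None, rttype=None, **kw):
    """ResolvedTriple whose resolved fields default to the originals."""
    return ResolvedTriple(
        source_name=src, source_type=stype, relation=rel,
        target_name=tgt, target_type=ttype, provenance=prov,
        source_resolved=rsrc or src, source_type_resolved=rstype or stype,
        relation_resolved=rrel or rel, target_resolved=rtgt or tgt,
        target_type_resolved=rttype or ttype, **kw,
    )


@pytest.fixture(scope="session")
def small_spec():
    return synthetic_corpus.CorpusSpec(
        n_articles=20, n_canonical_entities=30, seed=11
    )


@pytest.fixture(scope="session")
def small_corpus(small_spec):
    return synthetic_corpus.generate_corpus(small_spec)


@pytest.fixture(scope="session")
def small_extraction(small_corpus):
    docs, _ = small_corpus
    return extraction.extract_corpus(docs, extraction.TemplateExtractor())


@pytest.fixture(scope="session")
def small_resolved(small_corpus, small_extraction):
    _, truth = small_corpus
    table = dict(truth.entity_clusters)
    table.update(truth.relation_clusters)
    resolver = resolution.SynonymTableResolver(table)
    return resolution.resolve_corpus(
        small_extraction.triples, small_extraction.definitions,
        resolver=resolver, seed=3,
    )


@pytest.fixture(scope="session")
def reference_pipeline():
    """The reference study conditions run end to end once per session."""
    spec = synthetic_corpus.CorpusSpec()  # defaults: seed 7, 100 articles
    docs, truth = synthetic_corpus.generate_corpus(spec)
    extracted = extraction.extract_corpus(docs, extraction.TemplateExtractor())
    table = dict(truth.entity_clusters)
    table.update(truth.relation_clusters)
    result = resolution.resolve_corpus(
        extracted.triples, extracted.definitions,
        resolver=resolution.SynonymTableResolver(table), seed=0,
    )
    return {"docs": docs, "truth": truth, "extracted": extracted, "result": result}
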