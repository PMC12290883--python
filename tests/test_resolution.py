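"""Capped clustering, three-tier resolution and canonicalization rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litkg import grammar, resolution
from litkg.extraction import EntityDefinition
from litkg.resolution import (
    EntityRecord,
    HashedNgramEmbedder,
    IdentityResolver,
    AlwaysNewResolver,
    ResolutionError,
    ResolutionMap,
    SynonymTableResolver,
    apply_resolution,
    canonicalize_rules,
    capped_kmeans,
    resolve_entities,
    resolve_relations,
    resolve_types,
)

from conftest import make_raw


class TestEmbedder:
    def test_deterministic_and_unit_norm(self):
        emb = HashedNgramEmbedder()
        v1, v2 = emb.embed("heat factor"), emb.embed("heat factor")
        assert np.array_equal(v1, v2)
        assert np.isclose(np.linalg.norm(v1), 1.0)

    def test_case_variants_embed_identically(self):
        emb = HashedNgramEmbedder()
        assert np.allclose(emb.embed("Genes"), emb.embed("genes"))

    def test_related_closer_than_unrelated(self):
        emb = HashedNgramEmbedder()
        base = emb.embed("heat factor")
        assert base @ emb.embed("heat factors") > base @ emb.embed("zinc oxidase")


class TestCappedKmeans:
    def test_under_cap_single_leaf(self):
        X = np.random.default_rng(0).normal(size=(20, 4))
        tree = capped_kmeans(X, cap=30, seed=1)
        leaves = tree.leaves()
        assert len(leaves) == 1 and len(leaves[0]) == 20

    def test_two_blobs_respect_cap_and_purity(self):
        rng = np.random.default_rng(2)
        blob_a = rng.normal(loc=0.0, scale=0.05, size=(60, 3))
        blob_b = rng.normal(loc=10.0, scale=0.05, size=(40, 3))
        X = np.vstack([blob_a, blob_b])
        tree = capped_kmeans(X, cap=30, seed=0)
        for leaf in tree.leaves():
            assert len(leaf) <= 30
            # no leaf mixes blobs: all members on one side of the midpoint
            sides = {bool(i < 60) for i in leaf}
            assert len(sides) == 1

    def test_identical_points_force_arbitrary_split(self):
        X = np.ones((31, 3))
        tree = capped_kmeans(X, cap=30, seed=0)
        leaves = tree.leaves()
        assert len(leaves) == 2
        assert tree.any_forced

    @given(
        n=st.integers(1, 120),
        dim=st.integers(1, 5),
        cap=st.integers(1, 30),
        seed=st.integers(0, 10),
    )
    @settings(max_examples=25, deadline=None)
    def test_leaves_partition_and_respect_cap(self, n, dim, cap, seed):
        X = np.random.default_rng(seed).normal(size=(n, dim))
        tree = capped_kmeans(X, cap=cap, seed=seed)
        leaves = tree.leaves()
        assert all(len(leaf) <= cap for leaf in leaves)
        flat = sorted(i for leaf in leaves for i in leaf)
        assert flat == list(range(n))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            capped_kmeans(np.empty((0, 3)))


class TestTypeResolution:
    def test_small_table_is_identity(self):
        freq = {"gene": 10, "organ": 5, "metabolite": 2}
        state = resolve_types(freq, HashedNgramEmbedder(), IdentityResolver())
        assert sorted(state.reference_types) == sorted(freq)
        assert all(state.resolve(t) == t for t in freq)

    def test_always_new_resolver_keeps_every_type(self):
        freq = {f"type {i}": 50 - i for i in range(40)}
        state = resolve_types(freq, HashedNgramEmbedder(), AlwaysNewResolver(),
                              reference_size=30)
        assert len(state.reference_types) == 40
        assert all(state.resolve(t) == t for t in freq)

    def test_synonym_maps_gene_family_to_gene_group(self):
        freq = {"gene group": 100, "organ": 50, "metabolite": 40, "gene family": 2}
        resolver = SynonymTableResolver({"gene family": "gene group"})
        state = resolve_types(freq, HashedNgramEmbedder(), resolver, reference_size=3)
        assert state.resolve("gene family") == "gene group"
        assert "gene family" not in state.reference_types

    def test_mapping_is_idempotent(self):
        freq = {f"t{i}": 40 - i for i in range(35)}
        state = resolve_types(freq, HashedNgramEmbedder(), IdentityResolver(),
                              reference_size=10)
        for raw in freq:
            assert state.resolve(state.resolve(raw)) == state.resolve(raw)

    def test_empty_table_rejected(self):
        with pytest.raises(ResolutionError):
            resolve_types({}, HashedNgramEmbedder(), IdentityResolver())


class TestEntityResolution:
    def test_case_variants_merge_with_identity_resolver(self):
        records = [EntityRecord("Genes", "gene", "", 3), EntityRecord("genes", "gene", "", 5)]
        mapping = resolve_entities(records, HashedNgramEmbedder(), IdentityResolver())
        assert mapping["Genes"] == mapping["genes"] == "genes"

    def test_arabidopsis_synonyms_map_to_one_representative(self):
        table = {
            "Arabidopsis plants": "Arabidopsis thaliana",
            "Arabidopsis": "Arabidopsis thaliana",
            "A. thaliana": "Arabidopsis thaliana",
            "thale cress": "Arabidopsis thaliana",
            "Arabidopsis thaliana": "Arabidopsis thaliana",
        }
        records = [EntityRecord(name, "organism", "the model plant", 1) for name in table]
        mapping = resolve_entities(records, HashedNgramEmbedder(), SynonymTableResolver(table))
        assert set(mapping.values()) == {"Arabidopsis thaliana"}

    def test_non_partition_resolver_rejected(self):
        class BrokenResolver(IdentityResolver):
            def subcluster(self, items):
                subs = super().subcluster(items)
                return subs[:-1] if len(subs) > 1 else subs

        records = [EntityRecord("aa", "", "", 1), EntityRecord("bb", "", "", 1)]
        with pytest.raises(ResolutionError, match="partition"):
            resolve_entities(records, HashedNgramEmbedder(), BrokenResolver())


class TestRelationResolution:
    def test_single_relation_is_identity(self):
        triples = [make_raw("a", "binds", "b")]
        mapping = resolve_relations(triples, HashedNgramEmbedder(), IdentityResolver())
        assert mapping == {"binds": "binds"}

    def test_tense_synonyms_collapse(self):
        triples = (
            [make_raw("a", "causes", "b")] * 5
            + [make_raw("a", "cause", "b")] * 2
            + [make_raw("a", "caused", "b")]
        )
        table = {"cause": "causes", "caused": "causes", "causes": "causes"}
        mapping = resolve_relations(
            triples, HashedNgramEmbedder(), SynonymTableResolver(table)
        )
        assert set(mapping.values()) == {"causes"}


class TestCanonicalizeRules:
    def test_passive_rewritten_to_active_with_swap(self):
        result = canonicalize_rules([make_raw("B", "is regulated by", "A")])
        t = result.triples[0]
        assert (t.source_name, t.relation, t.target_name) == ("A", "regulates", "B")
        assert ("passive", "is regulated by", "regulates") in result.log
        # originals carry the swap so columns stay aligned
        o = result.originals[0]
        assert (o.source_name, o.target_name) == ("A", "B")

    def test_active_relation_untouched(self):
        result = canonicalize_rules([make_raw("x", "binds", "y")])
        t = result.triples[0]
        assert (t.source_name, t.relation, t.target_name) == ("x", "binds", "y")

    def test_irregular_passive_uses_config_map(self):
        result = canonicalize_rules([make_raw("B", "is bound by", "A")])
        assert result.triples[0].relation == "binds"

    def test_most_frequent_form_wins(self):
        triples = (
            [make_raw("a", "causes", "b")] * 10
            + [make_raw("a", "cause", "b")] * 4
            + [make_raw("a", "caused", "b")] * 2
        )
        result = canonicalize_rules(triples)
        assert {t.relation for t in result.triples} == {"causes"}

    def test_casing_normalized_to_most_frequent(self):
        triples = [make_raw("MYB46", "binds", "x")] * 3 + [make_raw("Myb46", "binds", "x")]
        result = canonicalize_rules(triples)
        assert {t.source_name for t in result.triples} == {"MYB46"}

    @pytest.mark.parametrize("seed", [0, 4, 9])
    def test_no_passive_relation_survives_on_generated_corpora(self, seed):
        from litkg import extraction, synthetic_corpus

        spec = synthetic_corpus.CorpusSpec(
            n_articles=15, n_canonical_entities=20, seed=seed, passive_rate=0.8
        )
        docs, _ = synthetic_corpus.generate_corpus(spec)
        extracted = extraction.extract_corpus(docs, extraction.TemplateExtractor())
        result = canonicalize_rules(extracted.triples)
        for t in result.triples:
            assert not grammar.PASSIVE_RELATION_RE.match(t.relation.casefold())


class TestApplyResolution:
    def test_identity_map_preserves_everything(self):
        triples = [make_raw("a", "binds", "b"), make_raw("b", "binds", "c")]
        rmap = ResolutionMap(
            {"gene": "gene"},
            {"a": "a", "b": "b", "c": "c"},
            {"binds": "binds"},
        )
        resolved = apply_resolution(triples, rmap)
        for t in resolved:
            assert t.source_name == t.source_resolved
            assert t.relation == t.relation_resolved
            assert t.target_name == t.target_resolved

    def test_merging_map_preserves_triples_reduces_entities(self):
        triples = [make_raw("a", "binds", "b"), make_raw("c", "binds", "b")]
        rmap = ResolutionMap({}, {"a": "a", "b": "b", "c": "a"}, {"binds": "binds"})
        resolved = apply_resolution(triples, rmap)
        assert len(resolved) == len(triples)
        originals = {t.source_name for t in resolved} | {t.target_name for t in resolved}
        merged = {t.source_resolved for t in resolved} | {t.target_resolved for t in resolved}
        assert len(merged) == len(originals) - 1

    def test_unmapped_surface_named_in_error(self):
        with pytest.raises(ResolutionError, match="mystery"):
            apply_resolution(
                [make_raw("mystery", "binds", "b")],
                ResolutionMap({}, {"b": "b"}, {"binds": "binds"}),
            )

    def test_resolution_map_is_idempotent(self, small_resolved):
        for mapping in (small_resolved.map.entity_map, small_resolved.map.relation_map):
            for surface, canonical in mapping.items():
                assert mapping[canonical] == canonical

    def test_map_json_round_trip(self, small_resolved, tmp_path):
        path = tmp_path / "map.json"
        small_resolved.map.to_json(path)
        back = ResolutionMap.from_json(path)
        assert back.entity_map == small_resolved.map.entity_map
        assert back.relation_map == small_resolved.map.relation_map


class TestPipelineRecovery:
    def test_small_corpus_recovered_exactly(self, small_corpus, small_resolved):
        _, truth = small_corpus
        resolved_keys = {t.resolved_key for t in small_resolved.resolved_triples}
        assert resolved_keys == set(truth.canonical_triples)

    def test_cluster_assignment_matches_ground_truth(self, small_corpus, small_resolved):
        from sklearn.metrics import adjusted_rand_score

        _, truth = small_corpus
        surfaces = sorted(truth.entity_clusters)
        full = small_resolved.full_entity_map()
        ari = adjusted_rand_score(
            [truth.entity_clusters[s] for s in surfaces],
            [full.get(s, s) for s in surfaces],
        )
        assert ari >= 0.95
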