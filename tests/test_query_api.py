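"""Search modes, neighborhoods, filtering with query retention, exports."""

import json

import numpy as np
import pytest

from litkg import query_api
from litkg.corpus_io import Document, Section
from litkg.kg_analytics import build_graph
from litkg.query_api import (
    CooccurrenceValidator,
    Query,
    QueryError,
    api_route,
    filter_subgraph,
    neighborhood,
    render_summary,
    search,
    to_json,
    to_tsv,
    validate_edge,
)

from conftest import make_resolved


@pytest.fixture()
def toy_kg():
    """PSAD1 hub with typed neighbors plus a disconnected pair."""
    triples = [
        make_resolved("PSAD1", "regulates", "growth", stype="gene identifier",
                      ttype="phenotype", prov="11_abstract"),
        make_resolved("PSAD1", "interacts with", "PSAE1", stype="gene identifier",
                      ttype="gene identifier", prov="12_intro"),
        make_resolved("auxin", "activates", "PSAD1", stype="metabolite",
                      ttype="gene identifier", prov="13_results"),
        make_resolved("enhanced heat tolerance", "causes", "survival",
                      stype="phenotype", ttype="phenotype", prov="14_abstract"),
    ]
    kg = build_graph(triples)
    kg.entities["PSAD1"].surface_forms.append("psaD1")
    return kg


class TestSearch:
    def test_normal_mode_matches_surface_case_insensitively(self, toy_kg):
        assert search(toy_kg, Query("normal", "psad1")) == ["PSAD1"]

    def test_substring_mode_matches_containment(self, toy_kg):
        hits = search(toy_kg, Query("substring", "heat tolerance"))
        assert hits == ["enhanced heat tolerance"]

    def test_absent_term_gives_empty_list(self, toy_kg):
        assert search(toy_kg, Query("normal", "nonexistent")) == []

    def test_title_mode_looks_up_pmid(self, toy_kg):
        hits = search(toy_kg, Query("title", "12"))
        assert set(hits) == {"PSAD1", "PSAE1"}

    def test_unknown_mode_rejected(self):
        with pytest.raises(QueryError):
            Query("fuzzy", "x")

    def test_author_mode_requires_metadata(self, toy_kg):
        corpus = [Document("11", sections=[Section("abstract", "x")])]
        with pytest.raises(QueryError, match="disabled"):
            search(toy_kg, Query("author", "mutwil"), corpus)

    def test_author_mode_with_metadata(self, toy_kg):
        corpus = [
            Document("11", sections=[], authors=["M Mutwil"]),
            Document("12", sections=[], authors=["A Other"]),
        ]
        hits = search(toy_kg, Query("author", "mutwil"), corpus)
        assert set(hits) == {"PSAD1", "growth"}

    def test_hits_ranked_by_degree(self, toy_kg):
        toy_kg.entities["growth"].surface_forms.append("psad1")
        hits = search(toy_kg, Query("normal", "psad1"))
        assert hits[0] == "PSAD1"  # degree 3 beats degree 1


class TestNeighborhood:
    def test_hub_with_three_neighbors_gives_four_nodes(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        assert sub.n_nodes == 4
        assert sub.n_papers == 3

    def test_unknown_id_rejected(self, toy_kg):
        with pytest.raises(QueryError):
            neighborhood(toy_kg, ["nope"])

    def test_isolated_node_counts(self):
        kg = build_graph([make_resolved("a", "binds", "b")])
        kg.entities["lonely"] = type(kg.entities["a"])(name="lonely", types=["gene"])
        sub = neighborhood(kg, ["lonely"])
        assert sub.n_nodes == 1 and sub.n_papers == 0

    @pytest.mark.parametrize("seed", range(8))
    def test_counts_equal_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        triples = []
        for _ in range(25):
            s, t = rng.choice(10, size=2, replace=False)
            triples.append(
                make_resolved(f"e{s}", "binds", f"e{t}", prov=f"{rng.integers(1, 6)}_abstract")
            )
        kg = build_graph(triples)
        root = sorted(kg.entities)[0]
        sub = neighborhood(kg, [root])
        nodes = {root} | {
            t.target_resolved for t in triples if t.source_resolved == root
        } | {t.source_resolved for t in triples if t.target_resolved == root}
        edges = {
            (t.source_resolved, t.relation_resolved, t.target_resolved)
            for t in triples
            if t.source_resolved in nodes and t.target_resolved in nodes
        }
        pmids = {k.split("_")[0] for e in edges for k in kg.edges[e].provenance}
        assert sub.node_ids == nodes
        assert sub.edge_keys == edges
        assert sub.n_papers == len(pmids)


class TestFilter:
    def test_query_node_of_unselected_type_kept_while_connected(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        out = filter_subgraph(sub, node_types=["phenotype"], edge_relations=["regulates"])
        # PSAD1 is "gene identifier" (unselected) but keeps its edge to growth
        assert out.node_ids == {"PSAD1", "growth"}
        assert out.edge_keys == {("PSAD1", "regulates", "growth")}

    def test_select_everything_is_identity(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        all_types = {toy_kg.entities[n].primary_type for n in sub.node_ids}
        all_rels = {k[1] for k in sub.edge_keys}
        out = filter_subgraph(sub, node_types=all_types, edge_relations=all_rels)
        assert out.node_ids == sub.node_ids and out.edge_keys == sub.edge_keys

    def test_no_selection_arguments_is_identity(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        out = filter_subgraph(sub)
        assert out.node_ids == sub.node_ids and out.edge_keys == sub.edge_keys

    def test_empty_selection_empties_result(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        out = filter_subgraph(sub, node_types=[], edge_relations=[])
        assert out.node_ids == set() and out.edge_keys == set()

    def test_hand_enumerated_selection(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        out = filter_subgraph(
            sub, node_types=["gene identifier"], edge_relations=["interacts with"]
        )
        assert out.node_ids == {"PSAD1", "PSAE1"}
        assert out.edge_keys == {("PSAD1", "interacts with", "PSAE1")}

    def test_filter_is_idempotent(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        once = filter_subgraph(sub, node_types=["gene identifier"])
        twice = filter_subgraph(once, node_types=["gene identifier"])
        assert once.node_ids == twice.node_ids and once.edge_keys == twice.edge_keys

    def test_paper_count_never_grows_under_filter(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        out = filter_subgraph(sub, node_types=["gene identifier"])
        assert out.n_papers <= sub.n_papers


class TestSummary:
    def test_empty_subgraph_gives_empty_summary(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        empty = filter_subgraph(sub, node_types=[], edge_relations=[])
        assert render_summary(empty) == ""

    def test_single_edge_statement_cites_provenance(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        out = filter_subgraph(sub, edge_relations=["regulates"])
        summary = render_summary(out)
        assert "PSAD1 regulates growth (11_abstract)" in summary

    def test_statements_biject_with_edges_under_any_filter(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        for rels in (None, ["regulates"], ["regulates", "activates"]):
            out = filter_subgraph(sub, edge_relations=rels)
            lines = [
                line for line in render_summary(out).splitlines()
                if line and not line.startswith("[")
            ]
            assert len(lines) == len(out.edge_keys)


class TestValidateEdge:
    def test_supported_when_sentence_cooccurs(self, toy_kg):
        edge = toy_kg.edges[("PSAD1", "regulates", "growth")]
        verdict = validate_edge(
            edge, "We found that PSAD1 regulates growth in roots. Other text.",
            CooccurrenceValidator(toy_kg),
        )
        assert verdict.supported
        assert "PSAD1 regulates growth" in verdict.sentences[0]

    def test_unsupported_without_comention(self, toy_kg):
        edge = toy_kg.edges[("PSAD1", "regulates", "growth")]
        verdict = validate_edge(
            edge, "PSAD1 is a gene. Growth happens elsewhere.",
            CooccurrenceValidator(toy_kg),
        )
        assert verdict.supported is False  # sentences never co-mention both

    def test_mock_verdict_equals_brute_force_scan(self, toy_kg):
        import re

        edge = toy_kg.edges[("PSAD1", "interacts with", "PSAE1")]
        text = "Intro sentence. PSAD1 binds PSAE1 strongly. Closing remark."
        verdict = validate_edge(edge, text, CooccurrenceValidator(toy_kg))
        brute = any(
            "psad1" in s.casefold() and "psae1" in s.casefold()
            for s in re.split(r"(?<=\.)\s+", text)
        )
        assert verdict.supported == brute

    def test_missing_source_text_rejected(self, toy_kg):
        edge = toy_kg.edges[("PSAD1", "regulates", "growth")]
        with pytest.raises(QueryError):
            validate_edge(edge, None, CooccurrenceValidator(toy_kg))


class TestExports:
    def test_api_route_shape(self):
        assert api_route(Query("normal", "psad1")) == "/api/normal/psad1"

    def test_empty_subgraph_serializes_to_valid_json(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        empty = filter_subgraph(sub, node_types=[], edge_relations=[])
        obj = json.loads(json.dumps(to_json(empty)))
        assert obj["nodes"] == [] and obj["edges"] == [] and obj["n_nodes"] == 0

    def test_json_round_trip_preserves_listed_fields(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        obj = json.loads(json.dumps(to_json(sub)))
        assert obj["n_nodes"] == sub.n_nodes
        assert obj["n_papers"] == sub.n_papers
        names = {n["name"] for n in obj["nodes"]}
        assert names == sub.node_ids
        keys = {(e["source"], e["relation"], e["target"]) for e in obj["edges"]}
        assert keys == sub.edge_keys
        assert obj["summary"] == render_summary(sub)

    def test_tsv_has_expected_columns_and_rows(self, toy_kg):
        sub = neighborhood(toy_kg, ["PSAD1"])
        lines = to_tsv(sub).strip().splitlines()
        assert lines[0] == "source\trelation\ttarget\tpmids\tevidence"
        assert len(lines) - 1 == len(sub.edge_keys)
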