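"""Event graphs, interaction distillation, merging and the bipartite network."""

import itertools
import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import metevent as me
from metevent.errors import NamingCollisionError
from metevent.network import (
    CONSUMES,
    PRODUCES,
    REACTION_DIR,
    InteractionPair,
    ProxyAllocator,
)


def pair(enzyme, metabolite, direction, **kw):
    return InteractionPair(enzyme, metabolite, direction, **kw)


class TestEventGraph:
    def test_worked_example_graph(self, glmm_doc):
        g = me.build_event_graph(glmm_doc)
        kinds = [d["kind"] for _, d in g.nodes(data=True)]
        assert kinds.count("entity") == 3 and kinds.count("event") == 2
        roles = sorted(d["role"] for _, _, d in g.edges(data=True))
        assert roles == ["Cause", "Theme", "Theme", "Theme"]

    def test_document_without_events(self):
        doc = me.AnnotatedDocument(
            "d", "leucine", [me.Entity("T1", me.METABOLITE, 0, 7, "leucine")], []
        )
        g = me.build_event_graph(doc)
        assert g.number_of_nodes() == 1 and g.number_of_edges() == 0

    def test_theme_only_production(self):
        doc = me.AnnotatedDocument(
            "d",
            "leucine synthesis",
            [me.Entity("T1", me.METABOLITE, 0, 7, "leucine")],
            [me.MetabolicEvent("E1", me.PRODUCTION, 8, 17, "synthesis", ("T1",))],
        )
        g = me.build_event_graph(doc)
        assert [d["role"] for _, _, d in g.edges(data=True)] == ["Theme"]


class TestToInteractions:
    def test_regulation_cause_propagates_to_reaction(self, glmm_doc):
        pairs = me.to_interactions(me.build_event_graph(glmm_doc))
        got = {(p.enzyme, p.metabolite, p.direction, p.role) for p in pairs}
        assert got == {
            ("GlmM", "glucosamine-1-phosphate", REACTION_DIR, "product"),
            ("GlmM", "glucosamine-6-phosphate", REACTION_DIR, "substrate"),
        }

    def test_production_with_cause(self):
        doc = me.AnnotatedDocument(
            "d",
            "leucine synthesis by T",
            [me.Entity("T1", me.METABOLITE, 0, 7, "leucine"),
             me.Entity("T2", me.GP, 21, 22, "T")],
            [me.MetabolicEvent("E1", me.PRODUCTION, 8, 17, "synthesis", ("T1",), ("T2",))],
        )
        (p,) = me.to_interactions(me.build_event_graph(doc))
        assert (p.enzyme, p.metabolite, p.direction) == ("T", "leucine", PRODUCES)
        assert p.provenance == (("d", ("E1",)),)

    def test_causeless_reaction_shares_one_proxy(self):
        doc = me.AnnotatedDocument(
            "d",
            "formation of a from b",
            [me.Entity("T1", me.METABOLITE, 13, 14, "a"),
             me.Entity("T2", me.METABOLITE, 20, 21, "b")],
            [me.MetabolicEvent("E1", me.REACTION, 0, 9, "formation", ("T1", "T2"))],
        )
        pairs = me.to_interactions(me.build_event_graph(doc))
        assert len(pairs) == 2
        assert {p.enzyme for p in pairs} == {"PROXY_1"}
        assert all(p.is_proxy for p in pairs)

    def test_explicit_nested_cause_kept_alongside_regulator(self):
        doc = me.AnnotatedDocument(
            "d",
            "A boosts b synthesis by C",
            [me.Entity("T1", me.GP, 0, 1, "A"),
             me.Entity("T2", me.METABOLITE, 9, 10, "b"),
             me.Entity("T3", me.GP, 24, 25, "C")],
            [me.MetabolicEvent("E1", me.PRODUCTION, 11, 20, "synthesis", ("T2",), ("T3",)),
             me.MetabolicEvent("E2", me.POSITIVE_REGULATION, 2, 8, "boosts", ("E1",), ("T1",))],
        )
        pairs = me.to_interactions(me.build_event_graph(doc))
        assert {(p.enzyme, p.metabolite) for p in pairs} == {("A", "b"), ("C", "b")}


class TestMerge:
    def test_duplicates_pool_provenance(self):
        pairs = [
            pair("T", "leucine", PRODUCES, provenance=(("doc1", ("E1",)),)),
            pair("T", "Leucine", PRODUCES, provenance=(("doc2", ("E3",)),)),
        ]
        merged = me.merge_interactions(pairs)
        assert len(merged) == 1
        assert merged[0].provenance == (("doc1", ("E1",)), ("doc2", ("E3",)))

    def test_synonyms_unify(self):
        syn = me.load_synonym_map(
            "tyrosine-repressible transaminase\ttyrB-encoded transaminase\n"
        )
        pairs = [
            pair("tyrosine-repressible transaminase", "leucine", PRODUCES),
            pair("tyrB-encoded transaminase", "leucine", PRODUCES),
        ]
        merged = me.merge_interactions(pairs, syn)
        assert len(merged) == 1
        assert merged[0].enzyme == "tyrb-encoded transaminase"

    def test_idempotent_and_order_insensitive(self):
        pairs = [
            pair("a", "x", PRODUCES), pair("A", "x", PRODUCES),
            pair("b", "y", CONSUMES), pair("a", "y", REACTION_DIR),
        ]
        once = me.merge_interactions(pairs)
        assert me.merge_interactions(once) == once
        assert me.merge_interactions(list(reversed(pairs))) == once


class TestConversions:
    def test_worked_example(self):
        pairs = [pair("T", "leucine", PRODUCES), pair("T", "2-KIC", CONSUMES)]
        assert me.infer_conversions(pairs) == [("2-KIC", "T", "leucine")]

    def test_producer_only_enzyme_yields_none(self):
        assert me.infer_conversions([pair("T", "leucine", PRODUCES)]) == []

    def test_cross_product_matches_brute_force(self):
        rng = random.Random(0)
        enzymes = ["e1", "e2", "e3"]
        mets = [f"m{i}" for i in range(6)]
        pairs = [
            pair(rng.choice(enzymes), rng.choice(mets), rng.choice([PRODUCES, CONSUMES]))
            for _ in range(20)
        ]
        merged = me.merge_interactions(pairs)
        expected = {
            (a.metabolite, a.enzyme, b.metabolite)
            for a, b in itertools.product(merged, merged)
            if a.enzyme == b.enzyme
            and a.direction == CONSUMES
            and b.direction == PRODUCES
            and a.metabolite != b.metabolite
        }
        got = me.infer_conversions(merged)
        assert set(got) == expected and len(got) == len(expected)


class TestBipartiteNetwork:
    def test_counts(self):
        pairs = [pair("e", f"m{i}", PRODUCES) for i in range(3)]
        net = me.build_network(pairs)
        assert (len(net.enzymes), len(net.metabolites), net.n_edges) == (1, 3, 3)

    def test_empty(self):
        net = me.build_network([])
        assert net.n_nodes == 0 and net.n_edges == 0

    def test_proxy_flag_preserved(self):
        net = me.build_network([pair("PROXY_1", "m", PRODUCES, is_proxy=True)])
        assert net.proxies == {"PROXY_1"}
        assert net.is_bipartite()

    def test_name_collision_rejected(self):
        with pytest.raises(NamingCollisionError):
            me.build_network([pair("x", "m", PRODUCES), pair("e", "x", CONSUMES)])

    def test_parallel_edges_by_direction(self):
        net = me.build_network([pair("e", "m", PRODUCES), pair("e", "m", CONSUMES)])
        assert net.n_edges == 2


class TestExport:
    def test_single_sif_line(self):
        net = me.build_network([pair("e", "m", PRODUCES)])
        assert me.export_network(net, "sif") == "e\tproduces\tm\n"

    def test_graphml_round_trip(self, glmm_doc):
        pairs = me.merge_interactions(me.to_interactions(me.build_event_graph(glmm_doc)))
        net = me.build_network(pairs)
        back = me.import_network(me.export_network(net, "graphml"), "graphml")
        assert back.pairs() == net.pairs()

    def test_tsv_sorted_and_round_trips(self):
        pairs = [pair("z", "m", PRODUCES), pair("a", "m", CONSUMES)]
        net = me.build_network(pairs)
        tsv = me.export_network(net, "tsv")
        body = tsv.splitlines()[1:]
        assert body == sorted(body)
        assert me.import_network(tsv, "tsv").pairs() == net.pairs()

    def test_unknown_format(self):
        with pytest.raises(me.MetEventError):
            me.export_network(me.build_network([]), "xlsx")


interaction_pairs = st.builds(
    InteractionPair,
    enzyme=st.sampled_from(["e1", "e2", "e3", "E1", "kinase a"]),
    metabolite=st.sampled_from(["m1", "m2", "m3", "m4"]),
    direction=st.sampled_from([PRODUCES, CONSUMES, REACTION_DIR]),
)


@settings(max_examples=80, derandomize=True, deadline=None)
@given(pairs=st.lists(interaction_pairs, max_size=15))
def test_network_is_always_bipartite_and_merge_idempotent(pairs):
    merged = me.merge_interactions(pairs)
    assert me.merge_interactions(merged) == merged
    net = me.build_network(merged)
    assert net.is_bipartite()
    assert net.n_edges == len(merged)


def test_proxy_ids_deterministic_first_appearance():
    alloc = ProxyAllocator()
    assert [alloc.new() for _ in range(3)] == ["PROXY_1", "PROXY_2", "PROXY_3"]
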