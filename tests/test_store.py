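"""Quad store: workspaces, registry, matching, transactions, serialization."""

import random

import pytest
from hypothesis import given, strategies as st
from rdflib import Literal, URIRef

from semcms.store import (
    ANY,
    GraphRegistrationError,
    QuadStore,
    QueryRefusedError,
    TransactionError,
    Workspace,
    create_store,
    quad_sort_key,
)

NGC = URIRef("https://ex.org/ng-class")


def reg(store, name, ws=Workspace.DRAFT):
    return store.register_graph(URIRef(f"https://ex.org/g/{name}"), NGC, ws)


def random_quads(rng, n, graphs):
    subjects = [URIRef(f"https://ex.org/s/{i}") for i in range(8)]
    preds = [URIRef(f"https://ex.org/p/{i}") for i in range(5)]
    objects = [URIRef(f"https://ex.org/o/{i}") for i in range(6)] + [Literal(str(i)) for i in range(4)]
    return [
        (rng.choice(subjects), rng.choice(preds), rng.choice(objects), rng.choice(graphs))
        for _ in range(n)
    ]


class TestWorkspacesAndRegistry:
    def test_store_has_the_six_workspaces(self):
        store = create_store()
        assert {ws.value for ws in store.workspaces} == {
            "ontology", "admin", "core", "draft", "published", "external_ontologies",
        }
        assert len(store.workspaces) == 6

    def test_two_stores_are_independent(self):
        a, b = create_store(), create_store()
        g = reg(a, "only-in-a")
        a.add(URIRef("https://ex.org/s"), URIRef("https://ex.org/p"), Literal("x"), g.iri)
        assert len(a) == 3 and len(b) == 0

    def test_persistence_roundtrip(self, tmp_path):
        path = str(tmp_path / "store.trig")
        store = create_store(path)
        g = reg(store, "persisted", Workspace.CORE)
        store.add(URIRef("https://ex.org/s"), URIRef("https://ex.org/p"), Literal("v"), g.iri)
        store.save(path)
        reloaded = create_store(path)
        assert reloaded.canonical_nquads() == store.canonical_nquads()
        assert reloaded.graph_ref(g.iri).workspace is Workspace.CORE

    def test_register_writes_instantiation_quad_into_same_workspace(self):
        store = create_store()
        ref = reg(store, "assertions", Workspace.DRAFT)
        assert ref.workspace is Workspace.DRAFT
        hits = store.match(ref.iri, ANY, ref.ng_class, ref.iri)
        assert len(hits) == 1

    def test_duplicate_registration_rejected(self):
        store = create_store()
        reg(store, "dup")
        with pytest.raises(GraphRegistrationError):
            reg(store, "dup")

    def test_each_graph_in_exactly_one_workspace(self):
        store = create_store()
        rng = random.Random(7)
        for i in range(20):
            reg(store, f"g{i}", rng.choice(list(Workspace)))
        per_ws = [len(store.graphs_in_workspace(ws)) for ws in Workspace]
        assert sum(per_ws) == len(store.graph_registry) == 20


class TestMatchAndReplace:
    def test_match_on_empty_store(self):
        assert create_store().match() == []

    def test_match_equals_naive_scan_on_random_store(self):
        rng = random.Random(1234)
        store = create_store()
        graphs = [reg(store, f"g{i}").iri for i in range(4)]
        quads = random_quads(rng, 200, graphs)
        for q in quads:
            store.add(*q)
        committed = set(quads) | {q for q in store}  # includes registry quads
        for _ in range(50):
            s = rng.choice([ANY, rng.choice([q[0] for q in quads])])
            p = rng.choice([ANY, rng.choice([q[1] for q in quads])])
            o = rng.choice([ANY, rng.choice([q[2] for q in quads])])
            g = rng.choice([ANY] + graphs)
            expected = sorted(
                (
                    q
                    for q in committed
                    if (s is ANY or q[0] == s)
                    and (p is ANY or q[1] == p)
                    and (o is ANY or q[2] == o)
                    and (g is ANY or q[3] == g)
                ),
                key=quad_sort_key,
            )
            assert store.match(s, p, o, g) == expected

    def test_replace_object_updates_single_value(self):
        store = create_store()
        g = reg(store, "a").iri
        s, p = URIRef("https://ex.org/s"), URIRef("https://ex.org/p")
        store.add(s, p, Literal("3"), g)
        removed = store.replace_object(g, s, p, Literal("5"))
        assert removed == 1
        assert [q[2] for q in store.match(s, p, ANY, g)] == [Literal("5")]

    def test_replace_object_inserts_when_absent(self):
        store = create_store()
        g = reg(store, "a").iri
        s, p = URIRef("https://ex.org/s"), URIRef("https://ex.org/p")
        assert store.replace_object(g, s, p, Literal("5")) == 0
        assert len(store.match(s, p, ANY, g)) == 1

    def test_replace_object_collapses_degenerate_duplicates(self):
        store = create_store()
        g = reg(store, "a").iri
        s, p = URIRef("https://ex.org/s"), URIRef("https://ex.org/p")
        store.add(s, p, Literal("1"), g)
        store.add(s, p, Literal("2"), g)
        assert store.replace_object(g, s, p, Literal("9")) == 2
        assert len(store.match(s, p, ANY, g)) == 1

    def test_replace_in_unregistered_graph_fails(self):
        store = create_store()
        with pytest.raises(GraphRegistrationError):
            store.replace_object(
                URIRef("https://ex.org/nope"), URIRef("https://ex.org/s"),
                URIRef("https://ex.org/p"), Literal("1"),
            )


class TestTransactions:
    def test_rollback_restores_canonical_dump(self):
        store = create_store()
        g = reg(store, "a").iri
        s, p = URIRef("https://ex.org/s"), URIRef("https://ex.org/p")
        store.add(s, p, Literal("3"), g)
        before = store.canonical_nquads()
        store.begin_transaction()
        store.replace_object(g, s, p, Literal("5"))
        store.add(s, URIRef("https://ex.org/p2"), Literal("x"), g)
        store.rollback()
        assert store.canonical_nquads() == before

    def test_commit_equals_eager_application(self):
        rng = random.Random(99)
        staged_store, eager_store = create_store(), create_store()
        graphs = []
        for st_ in (staged_store, eager_store):
            graphs = [reg(st_, f"g{i}").iri for i in range(2)]
        ops = random_quads(rng, 10, graphs)
        staged_store.begin_transaction()
        for q in ops:
            staged_store.add(*q)
            eager_store.add(*q)
        staged_store.commit()
        assert staged_store.canonical_nquads() == eager_store.canonical_nquads()

    def test_nested_begin_rejected(self):
        store = create_store()
        store.begin_transaction()
        with pytest.raises(TransactionError):
            store.begin_transaction()

    def test_commit_without_transaction_rejected(self):
        with pytest.raises(TransactionError):
            create_store().commit()


class TestSerialization:
    def test_empty_roundtrip(self):
        store = create_store()
        assert QuadStore.parse(store.serialize("trig"), "trig").canonical_nquads() == ""

    @pytest.mark.parametrize("fmt", ["trig", "nquads"])
    def test_roundtrip_identity(self, fmt):
        rng = random.Random(5)
        store = create_store()
        graphs = [reg(store, f"g{i}", ws) for i, ws in enumerate(Workspace)]
        for q in random_quads(rng, 80, [g.iri for g in graphs]):
            store.add(*q)
        again = QuadStore.parse(store.serialize(fmt), fmt)
        assert again.canonical_nquads() == store.canonical_nquads()
        assert {r.iri: r for r in again.graph_registry.values()} == {
            r.iri: r for r in store.graph_registry.values()
        }

    def test_nquads_line_count_equals_quad_count(self):
        store = create_store()
        g = reg(store, "a").iri
        for i in range(7):
            store.add(URIRef(f"https://ex.org/s{i}"), URIRef("https://ex.org/p"), Literal(str(i)), g)
        dump = store.canonical_nquads()
        assert len(dump.splitlines()) == len(store)

    def test_turtle_single_graph_export(self):
        store = create_store()
        g = reg(store, "a").iri
        store.add(URIRef("https://ex.org/s"), URIRef("https://ex.org/p"), Literal("v"), g)
        text = store.serialize_graph(g, "turtle")
        from rdflib import Graph

        parsed = Graph()
        parsed.parse(data=text, format="turtle")
        assert (URIRef("https://ex.org/s"), URIRef("https://ex.org/p"), Literal("v")) in parsed

    def test_malformed_parse_raises(self):
        with pytest.raises(Exception):
            QuadStore.parse("this is not rdf @@ ;;", "trig")


class TestPublishedQueries:
    def test_draft_data_invisible(self):
        store = create_store()
        g = reg(store, "draft", Workspace.DRAFT).iri
        store.add(URIRef("https://ex.org/s"), URIRef("https://ex.org/p"), Literal("v"), g)
        assert store.query_published([("?s", "?p", "?o")]) == []

    def test_visibility_flips_with_workspace(self):
        store = create_store()
        g = reg(store, "pub", Workspace.PUBLISHED).iri
        s, p = URIRef("https://ex.org/s"), URIRef("https://ex.org/p")
        store.add(s, p, Literal("v"), g)
        rows = store.query_published([(s, p, "?o")])
        assert rows == [{"?o": Literal("v")}]

    def test_explicit_draft_graph_refused(self):
        store = create_store()
        g = reg(store, "draft", Workspace.DRAFT).iri
        with pytest.raises(QueryRefusedError):
            store.query_published([("?s", "?p", "?o")], graphs=[g])

    def test_bgp_join_equals_bruteforce_assignment_enumeration(self):
        import itertools

        rng = random.Random(42)
        store = create_store()
        graphs = [reg(store, f"pub{i}", Workspace.PUBLISHED).iri for i in range(2)]
        quads = random_quads(rng, 100, graphs)
        for q in quads:
            store.add(*q)
        pool = [q for q in store if q[3] in set(graphs)]
        patterns = [
            ("?x", URIRef("https://ex.org/p/1"), "?y"),
            ("?y", URIRef("https://ex.org/p/2"), "?z"),
        ]
        # oracle: enumerate every assignment of pool quads to patterns and
        # keep the consistent ones
        expected = set()
        for combo in itertools.product(pool, repeat=len(patterns)):
            binding = {}
            ok = True
            for (ps, pp, po), (qs, qp, qo, _) in zip(patterns, combo):
                for pat, val in ((ps, qs), (pp, qp), (po, qo)):
                    if isinstance(pat, str) and pat.startswith("?"):
                        if binding.get(pat, val) != val:
                            ok = False
                            break
                        binding[pat] = val
                    elif pat != val:
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                expected.add(tuple(sorted((k, str(v)) for k, v in binding.items())))
        got = {
            tuple(sorted((k, str(v)) for k, v in row.items()))
            for row in store.query_published(patterns)
        }
        assert got == expected


@given(
    st.lists(
        st.tuples(st.integers(0, 5), st.integers(0, 3), st.integers(0, 5), st.integers(0, 2)),
        max_size=60,
    ),
    st.tuples(
        st.one_of(st.none(), st.integers(0, 5)),
        st.one_of(st.none(), st.integers(0, 3)),
        st.one_of(st.none(), st.integers(0, 5)),
        st.one_of(st.none(), st.integers(0, 2)),
    ),
)
def test_match_agrees_with_linear_scan(quad_indices, pattern_indices):
    """Property: match equals a naive linear scan for arbitrary stores."""
    store = create_store()
    graphs = [reg(store, f"g{i}") for i in range(3)]
    quads = [
        (
            URIRef(f"https://ex.org/s/{a}"),
            URIRef(f"https://ex.org/p/{b}"),
            Literal(str(c)),
            graphs[d].iri,
        )
        for a, b, c, d in quad_indices
    ]
    for q in quads:
        store.add(*q)
    si, pi, oi, gi = pattern_indices
    s = None if si is None else URIRef(f"https://ex.org/s/{si}")
    p = None if pi is None else URIRef(f"https://ex.org/p/{pi}")
    o = None if oi is None else Literal(str(oi))
    g = None if gi is None else graphs[gi].iri
    all_quads = {q for q in store}
    expected = sorted(
        (
            q
            for q in all_quads
            if (s is None or q[0] == s)
            and (p is None or q[1] == p)
            and (o is None or q[2] == o)
            and (g is None or q[3] == g)
        ),
        key=quad_sort_key,
    )
    assert store.match(s, p, o, g) == expected
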