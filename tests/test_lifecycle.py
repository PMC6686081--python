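"""Document life cycle: URI minting, graph networks, state machine.

The state machine is model-checked against an independently coded
reference automaton that works purely on multisets of version states:
exhaustive enumeration over every reachable (state, action) pair, plus
randomized action sequences.
"""

import random
from collections import Counter

import pytest
from rdflib import URIRef
from rdflib.namespace import RDF

from semcms import (
    TransitionAction,
    TransitionRefusedError,
    VersionState,
    Workspace,
    allowed_actions,
    generate_document_uri,
    version_dependent_graphs,
)
from tests.conftest import USER, Clock, make_plain_engine

# ---------------------------------------------------------------------------
# reference automaton: the ordered list of version states (version-number
# order), no engine machinery involved

CD, SD, RD, DD, CP, PP = "current", "saved", "recycle", "deleted", "published", "prev_published"


def ref_allowed(state: list[str]) -> set[str]:
    out = set()
    if CD in state:
        out |= {"backup", "to_bin", "publish"}
    if (SD in state or RD in state) and CD not in state:
        out.add("restore")
    if CP in state and not any(s in state for s in (CD, SD, RD)):
        out.add("revise")
    if RD in state:
        out.add("delete")
    return out


def _last_index(state: list[str], wanted: set[str]) -> int:
    for i in range(len(state) - 1, -1, -1):
        if state[i] in wanted:
            return i
    raise TransitionRefusedError(f"no version in {wanted}")


def ref_apply(state: list[str], action: str, variant: str | None) -> list[str] | None:
    """Apply an action to the ordered version-state list; None means the
    whole record is gone.  New versions are appended (version numbers only
    ever grow)."""
    s = list(state)
    if action == "backup":
        s.append(SD)
    elif action == "to_bin":
        i = _last_index(s, {SD} if variant == "saved" else {CD})
        s[i] = RD
    elif action == "restore":
        s[_last_index(s, {SD, RD})] = CD
    elif action == "delete":
        s[_last_index(s, {RD})] = DD
        if not any(x in s for x in (CD, SD, RD, CP, PP)):
            return None
    elif action == "publish":
        s = [PP if x in (CP, PP) else x for x in s if x in (CP, PP)]
        s.append(CP)
    elif action == "revise":
        s.append(CD)
    return s


ACTION_VARIANTS = [
    ("backup", None),
    ("to_bin", "current"),
    ("to_bin", "saved"),
    ("restore", None),
    ("delete", None),
    ("publish", None),
    ("revise", None),
]


def engine_state(record) -> list[str]:
    mapping = {
        VersionState.CURRENT_DRAFT: CD,
        VersionState.SAVED_DRAFT: SD,
        VersionState.RECYCLE_DRAFT: RD,
        VersionState.DELETED_DRAFT: DD,
        VersionState.CURRENT_PUBLISHED: CP,
        VersionState.PREVIOUSLY_PUBLISHED: PP,
    }
    return [mapping[v.state] for v in sorted(record.versions, key=lambda v: v.version_number)]


def engine_apply(engine, record, clock, action: str, variant: str | None) -> bool:
    """Apply the action variant through the engine; True if accepted."""
    ta = TransitionAction(action)
    target = None
    if action == "to_bin" and variant == "saved":
        saved = record.versions_in(VersionState.SAVED_DRAFT)
        if not saved:
            return False
        target = max(saved, key=lambda v: v.version_number).version_number
    try:
        engine.apply_transition(record, ta, target_version=target, user=USER, timestamp=clock())
    except TransitionRefusedError:
        return False
    return True


def run_sequence(actions: list[tuple[str, str | None]]):
    """Run one action sequence through engine and automaton in lockstep.

    Returns the list of (accepted, abstract-state-after) observations from
    both sides; asserts they agree step by step."""
    engine = make_plain_engine()
    clock = Clock()
    record = engine.create_document("plain", USER, clock())
    ref: list[str] | None = [CD]
    alive = True
    for action, variant in actions:
        if not alive or ref is None:
            break
        ref_ok = action in ref_allowed(ref)
        if ref_ok and action == "to_bin" and variant == "saved" and SD not in ref:
            ref_ok = False
        got_ok = engine_apply(engine, record, clock, action, variant)
        assert got_ok == ref_ok, (action, variant, ref)
        if ref_ok:
            ref = ref_apply(ref, action, variant)
            if ref is None:
                assert record.core_id not in engine.records
                alive = False
            else:
                assert engine_state(record) == ref, (action, variant)
                assert len(record.versions_in(VersionState.CURRENT_DRAFT)) <= 1
                assert len(record.versions_in(VersionState.CURRENT_PUBLISHED)) <= 1
    return engine, record if alive else None


class TestDocumentUri:
    def test_footnote_pattern(self):
        iri = generate_document_uri("https://ex.org", 7, "2019-08-08", "specimen", 1)
        assert str(iri) == "https://ex.org/resource/7-20190808-specimen-1"

    def test_deterministic_and_injective(self):
        a = generate_document_uri("https://ex.org", 7, "2019-08-08", "specimen", 1)
        b = generate_document_uri("https://ex.org", 7, "2019-08-08", "specimen", 1)
        c = generate_document_uri("https://ex.org", 8, "2019-08-08", "specimen", 1)
        assert a == b and a != c

    @pytest.mark.parametrize("bad", ["with/slash", "with-dash"])
    def test_doc_type_breaking_pattern_rejected(self, bad):
        with pytest.raises(ValueError):
            generate_document_uri("https://ex.org", 1, "2019-08-08", bad, 1)


class TestCreateDocument:
    def test_seven_graphs_listed_including_core_itself(self, engine, clock):
        record = engine.create_document("specimen", USER, clock())
        listed = engine.store.match(
            record.core_id, engine.vocab.resolve_label("lists named graph"),
            None, record.core_contents_ng.iri,
        )
        assert len(listed) == 7
        assert record.core_contents_ng.iri in {q[2] for q in listed}
        doc_graphs = [
            r for r in engine.store.graph_registry.values()
            if str(r.iri).startswith(str(record.core_id))
        ]
        assert len(doc_graphs) == 7

    def test_two_documents_have_disjoint_graphs(self, engine, clock):
        a = engine.create_document("specimen", USER, clock())
        b = engine.create_document("specimen", USER, clock())
        ga = {str(r.iri) for r in engine.store.graph_registry.values() if str(r.iri).startswith(str(a.core_id))}
        gb = {str(r.iri) for r in engine.store.graph_registry.values() if str(r.iri).startswith(str(b.core_id))}
        assert ga and gb and not (ga & gb)

    def test_composition_copy_isomorphic_to_template(self, engine, clock):
        from semcms import extract_form_template

        record = engine.create_document("specimen", USER, clock())
        template = extract_form_template(engine.model, "specimen")
        comp_g = record.current_draft.composition_ng.iri
        copied = {
            s: o for s, _, o, _ in engine.store.match(None, RDF.type, None, comp_g) if s != comp_g
        }
        template_nodes = list(template.walk())
        assert len(copied) == len(template_nodes)
        # class multiset preserved, instance IRIs all fresh
        assert Counter(map(str, copied.values())) == Counter(
            str(n.class_iri) for n in template_nodes
        )
        assert all(str(s).startswith(str(record.core_id)) for s in copied)

    def test_unknown_doc_type_rejected(self, engine, clock):
        with pytest.raises(Exception):
            engine.create_document("nope", USER, clock())

    def test_fresh_document_allows_backup_tobin_publish(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        assert allowed_actions(record) == {
            TransitionAction.BACKUP, TransitionAction.TO_BIN, TransitionAction.PUBLISH,
        }


class TestVersionDependentGraphs:
    def test_draft_graphs_in_draft_workspace(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        refs = version_dependent_graphs(record, record.current_draft)
        assert [r.workspace for r in refs] == [Workspace.DRAFT, Workspace.DRAFT]

    def test_published_graphs_in_published_workspace_and_draft_gone(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        draft_iris = [r.iri for r in version_dependent_graphs(record, record.current_draft)]
        plain_engine.apply_transition(record, TransitionAction.PUBLISH, user=USER, timestamp=clock())
        refs = version_dependent_graphs(record, record.current_published)
        assert [r.workspace for r in refs] == [Workspace.PUBLISHED, Workspace.PUBLISHED]
        for iri in draft_iris:
            assert iri not in plain_engine.store.graph_registry

    def test_foreign_version_rejected(self, plain_engine, clock):
        a = plain_engine.create_document("plain", USER, clock())
        b = plain_engine.create_document("plain", USER, clock())
        with pytest.raises(Exception):
            version_dependent_graphs(a, b.current_draft)


class TestStateMachineScenarios:
    def test_tobin_then_restore_recovers_current_draft(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        plain_engine.apply_transition(record, TransitionAction.TO_BIN, user=USER, timestamp=clock())
        assert record.current_draft is None
        plain_engine.apply_transition(record, TransitionAction.RESTORE, user=USER, timestamp=clock())
        assert record.current_draft is not None

    def test_first_publish_yields_single_current_published(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        plain_engine.apply_transition(record, TransitionAction.PUBLISH, user=USER, timestamp=clock())
        assert len(record.versions_in(VersionState.CURRENT_PUBLISHED)) == 1
        assert record.versions_in(VersionState.PREVIOUSLY_PUBLISHED) == []

    def test_publish_erases_every_draft_graph(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        plain_engine.apply_transition(record, TransitionAction.BACKUP, user=USER, timestamp=clock())
        plain_engine.apply_transition(record, TransitionAction.PUBLISH, user=USER, timestamp=clock())
        doc_graphs = [
            r for r in plain_engine.store.graph_registry.values()
            if str(r.iri).startswith(str(record.core_id))
        ]
        assert all(r.workspace is not Workspace.DRAFT for r in doc_graphs)

    def test_previously_published_point_to_current(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        plain_engine.apply_transition(record, TransitionAction.PUBLISH, user=USER, timestamp=clock())
        for _ in range(2):
            plain_engine.apply_transition(record, TransitionAction.REVISE, user=USER, timestamp=clock())
            plain_engine.apply_transition(record, TransitionAction.PUBLISH, user=USER, timestamp=clock())
        pointer = plain_engine.vocab.resolve_label("points to current published version")
        current = record.current_published
        for v in record.versions_in(VersionState.PREVIOUSLY_PUBLISHED):
            hits = plain_engine.store.match(v.version_iri, pointer, None, record.provenance_ng.iri)
            assert [q[2] for q in hits] == [current.version_iri]

    def test_delete_keeps_only_delete_metadata(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        plain_engine.apply_transition(record, TransitionAction.BACKUP, user=USER, timestamp=clock())
        plain_engine.apply_transition(
            record, TransitionAction.TO_BIN, target_version=2, user=USER, timestamp=clock()
        )
        plain_engine.apply_transition(
            record, TransitionAction.DELETE, target_version=2, user=USER, timestamp=clock()
        )
        v2 = record.version(2)
        assert v2.state is VersionState.DELETED_DRAFT
        assert v2.composition_ng is None and v2.assertions_ng is None
        # the delete process stays visible in the status chain
        _, statuses = plain_engine.change_history(record)
        from semcms import WorkflowAction

        assert statuses[-1].transition_process is WorkflowAction.DELETE

    def test_deleting_last_version_removes_whole_record(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        core = record.core_id
        plain_engine.apply_transition(record, TransitionAction.TO_BIN, user=USER, timestamp=clock())
        plain_engine.apply_transition(record, TransitionAction.DELETE, user=USER, timestamp=clock())
        assert core not in plain_engine.records
        assert not [
            r for r in plain_engine.store.graph_registry.values() if str(r.iri).startswith(str(core))
        ]

    def test_revise_requires_no_draft_version(self, plain_engine, clock):
        record = plain_engine.create_document("plain", USER, clock())
        plain_engine.apply_transition(record, TransitionAction.PUBLISH, user=USER, timestamp=clock())
        plain_engine.apply_transition(record, TransitionAction.REVISE, user=USER, timestamp=clock())
        with pytest.raises(TransitionRefusedError):
            plain_engine.apply_transition(record, TransitionAction.REVISE, user=USER, timestamp=clock())


class TestModelCheck:
    def test_exhaustive_reachable_state_action_agreement(self):
        """Every (reachable abstract state, action variant) pair behaves
        identically in the engine and the reference automaton (depth <= 6)."""
        seen: set[tuple] = {(CD,)}
        frontier: list[tuple[tuple, list]] = [((CD,), [])]
        checked = 0
        depth = 0
        while frontier and depth < 6:
            depth += 1
            next_frontier = []
            for state_key, path in frontier:
                for action, variant in ACTION_VARIANTS:
                    engine, record = run_sequence(path + [(action, variant)])
                    checked += 1
                    if record is None:
                        continue
                    key = tuple(engine_state(record))
                    if key not in seen:
                        seen.add(key)
                        next_frontier.append((key, path + [(action, variant)]))
            frontier = next_frontier
        assert checked >= 50  # the automaton has been exercised broadly

    def test_random_sequences_agree_with_reference(self):
        rng = random.Random(2026)
        for _ in range(500):
            length = rng.randint(1, 8)
            actions = [ACTION_VARIANTS[rng.randrange(len(ACTION_VARIANTS))] for _ in range(length)]
            run_sequence(actions)
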