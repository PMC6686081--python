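"""Versions-and-provenance and change-history knowledge graphs.

Two tracking structures are written for every document:

* the *versions and provenance* graph: one entry per document version with
  its creator, creation time, predecessor version and the set of
  contributors;
* the *change-history* graph, holding two linear chains: the chain of
  entry states in time (each editing step fills the newest state's logged
  change - timestamp, user, session, input field, new value - and appends
  a fresh state with a yet empty logged change), and the chain of document
  statuses in time, linked by the transition process that led from one
  status to the next.

Predicates are surrogate IRIs minted in the engine's namespace with labels
mirroring the pav/dcterms/ti/tvc semantics the graphs express.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

from .store import ANY, QuadStore, Term
from .vocabulary import Vocabulary, WorkflowAction

if TYPE_CHECKING:  # pragma: no cover
    from .lifecycle import DocumentRecord, DocumentVersion


class ChainIntegrityError(Exception):
    pass


@dataclass(frozen=True)
class ChangeLogEntry:
    """One logged editing step; all five fields are mandatory."""

    timestamp: str  # UTC ISO 8601
    user: URIRef
    session: str
    input_field: URIRef
    new_value: Term

    def require_complete(self) -> None:
        for name in ("timestamp", "user", "session", "input_field", "new_value"):
            if getattr(self, name) in (None, ""):
                raise ValueError(f"change-log entry missing field: {name}")


@dataclass(frozen=True)
class EntryStateNode:
    iri: URIRef
    predecessor: Optional[URIRef]
    logged_change: Optional[ChangeLogEntry]


@dataclass(frozen=True)
class StatusNode:
    iri: URIRef
    status: str  # status label
    transition_process: Optional[WorkflowAction]
    predecessor: Optional[URIRef]
    timestamp: Optional[str] = None


@dataclass(frozen=True)
class ProvenanceEntry:
    version_iri: URIRef
    previous_version: Optional[URIRef]
    created_by: URIRef
    created_on: str
    contributors: frozenset[URIRef]


# ---------------------------------------------------------------------------
# versions-and-provenance graph


def record_version_provenance(
    store: QuadStore,
    vocab: Vocabulary,
    record: "DocumentRecord",
    version: "DocumentVersion",
    user: URIRef,
    timestamp: str,
) -> ProvenanceEntry:
    """Write the provenance entry for a (new) version; the previous version
    is the chronologically latest version already recorded."""
    g = record.provenance_ng.iri
    r = vocab.resolve_label
    prior = [
        s
        for s, _, _, _ in store.match(ANY, RDF.type, r("document version"), g)
        if s != version.version_iri
    ]
    previous: Optional[URIRef] = None
    if prior:
        # versions carry monotonically increasing version numbers
        def vnum(iri: URIRef) -> int:
            v = store.value(iri, r("has version number"), g)
            return int(str(v)) if v is not None else 0

        previous = max(prior, key=vnum)

    store.add(version.version_iri, RDF.type, r("document version"), g)
    store.add(version.version_iri, r("has version number"), Literal(version.version_number), g)
    store.add(version.version_iri, r("created by"), user, g)
    store.add(version.version_iri, r("created on"), Literal(timestamp, datatype=XSD.dateTime), g)
    store.add(version.version_iri, r("interval start"), Literal(timestamp, datatype=XSD.dateTime), g)
    store.add(version.version_iri, r("contributed by"), user, g)
    if previous is not None:
        store.add(version.version_iri, r("previous version"), previous, g)
        store.add(previous, r("interval end"), Literal(timestamp, datatype=XSD.dateTime), g)
    return get_provenance_entry(store, vocab, record, version.version_iri)


def get_provenance_entry(
    store: QuadStore, vocab: Vocabulary, record: "DocumentRecord", version_iri: URIRef
) -> ProvenanceEntry:
    g = record.provenance_ng.iri
    r = vocab.resolve_label
    prev = store.value(version_iri, r("previous version"), g)
    created_by = store.value(version_iri, r("created by"), g)
    created_on = store.value(version_iri, r("created on"), g)
    contributors = frozenset(
        q[2] for q in store.match(version_iri, r("contributed by"), ANY, g)
    )
    return ProvenanceEntry(
        version_iri=version_iri,
        previous_version=prev,
        created_by=created_by,
        created_on=str(created_on) if created_on is not None else "",
        contributors=contributors,
    )


def provenance_chain(
    store: QuadStore, vocab: Vocabulary, record: "DocumentRecord"
) -> list[ProvenanceEntry]:
    """All provenance entries, walked newest-to-oldest along previous-version
    links, returned oldest first."""
    g = record.provenance_ng.iri
    r = vocab.resolve_label
    versions = [s for s, _, _, _ in store.match(ANY, RDF.type, r("document version"), g)]
    if not versions:
        return []
    pointed_to = {store.value(v, r("previous version"), g) for v in versions}
    heads = [v for v in versions if v not in pointed_to]
    if len(heads) != 1:
        raise ChainIntegrityError(f"provenance chain has {len(heads)} heads")
    chain = []
    cur: Optional[URIRef] = heads[0]
    seen: set[URIRef] = set()
    while cur is not None:
        if cur in seen:
            raise ChainIntegrityError("cycle in provenance chain")
        seen.add(cur)
        chain.append(get_provenance_entry(store, vocab, record, cur))
        cur = store.value(cur, r("previous version"), g)
    chain.reverse()
    return chain


# ---------------------------------------------------------------------------
# change-history graph: entry-state chain


def init_change_log(store: QuadStore, vocab: Vocabulary, record: "DocumentRecord") -> EntryStateNode:
    """Create the initial entry state (with a yet empty logged change)."""
    g = record.change_log_ng.iri
    r = vocab.resolve_label
    node = URIRef(f"{record.core_id}/entry-state/1")
    store.add(node, RDF.type, r("entry state in time"), g)
    return EntryStateNode(node, None, None)


def _entry_state_nodes(store: QuadStore, vocab: Vocabulary, record: "DocumentRecord") -> list[URIRef]:
    g = record.change_log_ng.iri
    return [s for s, _, _, _ in store.match(ANY, RDF.type, vocab.resolve_label("entry state in time"), g)]


def _newest_entry_state(store: QuadStore, vocab: Vocabulary, record: "DocumentRecord") -> URIRef:
    g = record.change_log_ng.iri
    r = vocab.resolve_label
    nodes = _entry_state_nodes(store, vocab, record)
    empty = [n for n in nodes if store.value(n, r("has logged change"), g) is None]
    if len(empty) != 1:
        raise ChainIntegrityError(
            f"entry-state chain must have exactly one node with an empty logged change, found {len(empty)}"
        )
    return empty[0]


def append_change_log(
    store: QuadStore, vocab: Vocabulary, record: "DocumentRecord", entry: ChangeLogEntry
) -> EntryStateNode:
    """Log one editing step: fill the newest entry state's logged change and
    append a fresh state with an empty logged change."""
    entry.require_complete()
    g = record.change_log_ng.iri
    r = vocab.resolve_label
    newest = _newest_entry_state(store, vocab, record)
    n = len(_entry_state_nodes(store, vocab, record))
    change = URIRef(f"{record.core_id}/change/{n}")
    store.add(change, RDF.type, r("logged change"), g)
    store.add(change, r("logged on"), Literal(entry.timestamp, datatype=XSD.dateTime), g)
    store.add(change, r("logged by user"), entry.user, g)
    store.add(change, r("logged in session"), Literal(entry.session), g)
    store.add(change, r("changed input field"), entry.input_field, g)
    store.add(change, r("new value"), entry.new_value, g)
    store.add(newest, r("has logged change"), change, g)
    fresh = URIRef(f"{record.core_id}/entry-state/{n + 1}")
    store.add(fresh, RDF.type, r("entry state in time"), g)
    store.add(fresh, r("previous entry state"), newest, g)
    return EntryStateNode(fresh, newest, None)


def entry_state_chain(
    store: QuadStore, vocab: Vocabulary, record: "DocumentRecord"
) -> list[EntryStateNode]:
    """The entry-state chain, oldest first; validates linearity."""
    g = record.change_log_ng.iri
    r = vocab.resolve_label
    nodes = _entry_state_nodes(store, vocab, record)
    if not nodes:
        return []
    preds = {n: store.value(n, r("previous entry state"), g) for n in nodes}
    referenced = [p for p in preds.values() if p is not None]
    if len(referenced) != len(set(referenced)):
        raise ChainIntegrityError("entry-state chain is not linear")
    heads = [n for n in nodes if n not in set(referenced)]
    tails = [n for n in nodes if preds[n] is None]
    if len(heads) != 1 or len(tails) != 1:
        raise ChainIntegrityError("entry-state chain must have exactly one head and one tail")
    # walk from the newest (head = node nobody references) back, then reverse
    order = []
    cur: Optional[URIRef] = heads[0]
    seen: set[URIRef] = set()
    while cur is not None:
        if cur in seen:
            raise ChainIntegrityError("cycle in entry-state chain")
        seen.add(cur)
        order.append(cur)
        cur = preds[cur]
    if len(order) != len(nodes):
        raise ChainIntegrityError("broken entry-state chain")
    order.reverse()
    out = []
    for node in order:
        change = store.value(node, r("has logged change"), g)
        logged = None
        if change is not None:
            logged = ChangeLogEntry(
                timestamp=str(store.value(change, r("logged on"), g)),
                user=store.value(change, r("logged by user"), g),
                session=str(store.value(change, r("logged in session"), g)),
                input_field=store.value(change, r("changed input field"), g),
                new_value=store.value(change, r("new value"), g),
            )
        out.append(EntryStateNode(node, preds[node], logged))
    return out


# ---------------------------------------------------------------------------
# change-history graph: status chain


def append_status_transition(
    store: QuadStore,
    vocab: Vocabulary,
    record: "DocumentRecord",
    action: Optional[WorkflowAction],
    new_status: str,
    timestamp: str,
) -> StatusNode:
    """Append a document-status node, linked to its predecessor through the
    transition process that produced it (the first node has neither)."""
    g = record.change_log_ng.iri
    r = vocab.resolve_label
    existing = status_chain(store, vocab, record)
    n = len(existing) + 1
    node = URIRef(f"{record.core_id}/status/{n}")
    store.add(node, RDF.type, r("document status in time"), g)
    store.add(node, r("has document status"), vocab.status_term(new_status), g)
    store.add(node, r("logged on"), Literal(timestamp, datatype=XSD.dateTime), g)
    prev = existing[-1].iri if existing else None
    if prev is not None:
        if action is None:
            raise ValueError("non-initial status nodes require a transition process")
        store.add(node, r("previous document status"), prev, g)
        store.add(node, r("status transition process"), vocab.workflow_action(action), g)
    return StatusNode(node, new_status, action, prev, timestamp)


def status_chain(store: QuadStore, vocab: Vocabulary, record: "DocumentRecord") -> list[StatusNode]:
    """The status chain, oldest first; validates linearity."""
    g = record.change_log_ng.iri
    r = vocab.resolve_label
    nodes = [s for s, _, _, _ in store.match(ANY, RDF.type, r("document status in time"), g)]
    if not nodes:
        return []
    preds = {n: store.value(n, r("previous document status"), g) for n in nodes}
    referenced = set(p for p in preds.values() if p is not None)
    heads = [n for n in nodes if n not in referenced]
    if len(heads) != 1:
        raise ChainIntegrityError("status chain must have exactly one head")
    order = []
    cur: Optional[URIRef] = heads[0]
    seen: set[URIRef] = set()
    while cur is not None:
        if cur in seen:
            raise ChainIntegrityError("cycle in status chain")
        seen.add(cur)
        order.append(cur)
        cur = preds[cur]
    if len(order) != len(nodes):
        raise ChainIntegrityError("broken status chain")
    order.reverse()
    out = []
    for node in order:
        status_iri = store.value(node, r("has document status"), g)
        proc_iri = store.value(node, r("status transition process"), g)
        ts = store.value(node, r("logged on"), g)
        out.append(
            StatusNode(
                iri=node,
                status=vocab.label_of(status_iri) if status_iri is not None else "",
                transition_process=vocab.workflow_action_of(proc_iri) if proc_iri is not None else None,
                predecessor=preds[node],
                timestamp=str(ts) if ts is not None else None,
            )
        )
    return out


# ---------------------------------------------------------------------------
# workflow-action dispatch


def run_workflow_action(engine, action: WorkflowAction, context: dict) -> dict:
    """Dispatch a workflow action's tracking bundle.

    For 'edit': add the user to the version's contributor set and to the
    user's own contribution list in the admin workspace, then log the edit
    in the change-history graph.  Lifecycle transitions are dispatched to
    the document life-cycle machinery.
    """
    from . import lifecycle

    store: QuadStore = engine.store
    vocab: Vocabulary = engine.vocab
    record: "DocumentRecord" = context["record"]
    r = vocab.resolve_label

    if action is WorkflowAction.EDIT:
        version = context["version"]
        user = context["user"]
        g = record.provenance_ng.iri
        if not store.match(version.version_iri, r("contributed by"), user, g):
            store.add(version.version_iri, r("contributed by"), user, g)
        contrib_g = engine.user_contributions_graph(user)
        if not store.match(user, r("contributed to document"), record.core_id, contrib_g):
            store.add(user, r("contributed to document"), record.core_id, contrib_g)
        entry = ChangeLogEntry(
            timestamp=context["timestamp"],
            user=user,
            session=context["session"],
            input_field=context["input_field"],
            new_value=context["new_value"],
        )
        node = append_change_log(store, vocab, record, entry)
        return {"action": action, "entry_state": node}

    # lifecycle transitions
    ta = lifecycle.TransitionAction(action.value)
    lifecycle.apply_transition(
        engine,
        record,
        ta,
        target_version=context.get("target_version"),
        user=context["user"],
        timestamp=context["timestamp"],
    )
    return {"action": action}


def get_change_history(
    store: QuadStore, vocab: Vocabulary, record: "DocumentRecord"
) -> tuple[list[ChangeLogEntry], list[StatusNode]]:
    """Ordered logged changes plus the ordered status chain."""
    states = entry_state_chain(store, vocab, record)
    entries = [s.logged_change for s in states if s.logged_change is not None]
    return entries, status_chain(store, vocab, record)
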