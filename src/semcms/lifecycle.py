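"""Document and version management: URI minting, graph networks, life cycle.

A document is a record with a growing list of versions.  Each version is in
one of six states (current/saved/recycle/deleted draft, current/previously
published); the allowed transitions are:

* ``create``  -> a new record with one current draft version
* ``backup``  -> deep-copy the current draft as a saved draft
* ``to_bin``  -> move the current (or a saved) draft to the recycle bin
* ``restore`` -> make a saved/recycle draft the current draft (only if no
  current draft exists)
* ``delete``  -> erase a recycle draft's data, keeping only the metadata of
  the delete process; the whole record disappears once nothing but deleted
  drafts remain
* ``publish`` -> mint a current published version from the current draft,
  erase every draft version, demote the prior published version and point
  all previously published versions at the new one
* ``revise``  -> start a new current draft from the current published
  version (only if no draft version exists)

At all times a record has at most one current draft and at most one current
published version.  Every transition appends one status node to the
document's change-history graph.

Creating a document registers its named-graph network: five
version-independent graphs in the core workspace (core document contents,
versions and provenance, change log, document-specific access rights, core
document individuals) and two version-dependent graphs per draft version
(document composition - a deep copy of the entry-form template with fresh
instance IRIs - and assertions) in the draft workspace.  The core document
contents graph lists all of them, itself included.
"""

from __future__ import annotations

import datetime
import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Union

from rdflib import Literal, URIRef
from rdflib.namespace import RDF

from . import provenance
from .source_loader import EntryComponentTemplate, extract_form_template
from .store import ANY, NamedGraphRef, QuadStore, Workspace
from .vocabulary import NamedGraphClass, Vocabulary, WorkflowAction

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Engine


class LifecycleError(Exception):
    pass


class TransitionRefusedError(LifecycleError):
    """An action was requested that the life-cycle rules forbid."""


class VersionState(enum.Enum):
    CURRENT_DRAFT = "current draft version"
    SAVED_DRAFT = "saved draft version"
    RECYCLE_DRAFT = "recycle draft version"
    DELETED_DRAFT = "deleted draft version"
    CURRENT_PUBLISHED = "current published version"
    PREVIOUSLY_PUBLISHED = "previously published version"


DRAFT_STATES = frozenset(
    {VersionState.CURRENT_DRAFT, VersionState.SAVED_DRAFT, VersionState.RECYCLE_DRAFT}
)


class TransitionAction(enum.Enum):
    CREATE = "create"
    BACKUP = "backup"
    TO_BIN = "to_bin"
    RESTORE = "restore"
    DELETE = "delete"
    PUBLISH = "publish"
    REVISE = "revise"

    @property
    def workflow_action(self) -> WorkflowAction:
        return WorkflowAction(self.value)


@dataclass
class DocumentVersion:
    version_iri: URIRef
    version_number: int
    state: VersionState
    composition_ng: Optional[NamedGraphRef]
    assertions_ng: Optional[NamedGraphRef]
    created_on: str


@dataclass
class DocumentRecord:
    core_id: URIRef
    doc_type: str
    unique_number: int
    owner: URIRef
    core_contents_ng: NamedGraphRef
    provenance_ng: NamedGraphRef
    change_log_ng: NamedGraphRef
    access_ng: NamedGraphRef
    individuals_ng: NamedGraphRef
    versions: list[DocumentVersion] = field(default_factory=list)

    def versions_in(self, *states: VersionState) -> list[DocumentVersion]:
        return [v for v in self.versions if v.state in states]

    @property
    def current_draft(self) -> Optional[DocumentVersion]:
        vs = self.versions_in(VersionState.CURRENT_DRAFT)
        return vs[0] if vs else None

    @property
    def current_published(self) -> Optional[DocumentVersion]:
        vs = self.versions_in(VersionState.CURRENT_PUBLISHED)
        return vs[0] if vs else None

    def version(self, number: int) -> DocumentVersion:
        for v in self.versions:
            if v.version_number == number:
                return v
        raise LifecycleError(f"no version {number} in document {self.core_id}")


def generate_document_uri(
    namespace: str,
    unique_number: int,
    date: Union[str, datetime.date],
    doc_type: str,
    version_number: int,
) -> URIRef:
    """Mint a document-version IRI following
    ``namespace/resource/UniqueNumber-YearMonthDay-DocumentType-VersionNumber``."""
    if unique_number < 1 or version_number < 1:
        raise ValueError("unique_number and version_number must be >= 1")
    if "/" in doc_type or "-" in doc_type:
        raise ValueError(f"document type {doc_type!r} would break the URI pattern")
    if isinstance(date, str):
        date = datetime.date.fromisoformat(date[:10])
    stamp = date.strftime("%Y%m%d")
    return URIRef(f"{namespace.rstrip('/')}/resource/{unique_number}-{stamp}-{doc_type}-{version_number}")


# ---------------------------------------------------------------------------
# graph-network setup


def _register_doc_graph(
    engine: "Engine", iri: URIRef, ngc: NamedGraphClass, workspace: Optional[Workspace] = None
) -> NamedGraphRef:
    ws = workspace or engine.ng_workspace(ngc)
    return engine.store.register_graph(iri, engine.vocab.ng_class(ngc), ws)


def _copy_template(
    engine: "Engine",
    record_core_id: URIRef,
    template: EntryComponentTemplate,
    comp_g: URIRef,
    indiv_g: URIRef,
) -> None:
    """Deep-copy the entry-form template into a composition graph, minting a
    fresh instance IRI per component; slot values that name a domain class
    are resolved to this document's specific individual of that class."""
    store, vocab = engine.store, engine.vocab
    cmd = vocab.cmd
    empty = vocab.var("SPrO_VARIABLE: empty")
    mapping: dict[URIRef, URIRef] = {}
    nodes = list(template.walk())
    for k, node in enumerate(nodes, start=1):
        mapping[node.instance_iri] = URIRef(f"{record_core_id}/component/{k}")
    for node in nodes:
        inst = mapping[node.instance_iri]
        store.add(inst, RDF.type, node.class_iri, comp_g)
        store.add(inst, RDF.type, node.class_iri, indiv_g)
        if node.parent is not None and node.parent in mapping:
            store.add(inst, cmd("entry component of"), mapping[node.parent], comp_g)
        store.add(inst, cmd("has position in entry component"), Literal(str(node.position)), comp_g)
        for slot_label, value in node.associated_slots.items():
            if isinstance(value, URIRef) and value != empty:
                # a class reference: resolve to the document's individual
                value = engine.document_individual(
                    None, value, mint=True, indiv_g=indiv_g, core_id=record_core_id
                )
            store.add(inst, cmd(slot_label), value, comp_g)


def _copy_graph(store: QuadStore, src: URIRef, dst: URIRef) -> None:
    for s, p, o, _ in store.match(g=src):
        if s == src:  # skip the graph's self-describing statements
            continue
        store.add(s, p, o, dst)


def _list_graph(engine: "Engine", record: DocumentRecord, graph_iri: URIRef) -> None:
    engine.store.add(
        record.core_id,
        engine.vocab.resolve_label("lists named graph"),
        graph_iri,
        record.core_contents_ng.iri,
    )


def _unlist_graph(engine: "Engine", record: DocumentRecord, graph_iri: URIRef) -> None:
    engine.store.remove(
        record.core_id,
        engine.vocab.resolve_label("lists named graph"),
        graph_iri,
        record.core_contents_ng.iri,
    )


def create_document(engine: "Engine", doc_type: str, user: URIRef, timestamp: str) -> DocumentRecord:
    """Create a document of ``doc_type``: mint its IRIs, set up its named
    graph network, deep-copy the entry-form template, grant the creator the
    edit right and write the initial provenance and status entries."""
    template = extract_form_template(engine.model, doc_type)
    store, vocab = engine.store, engine.vocab
    n = engine.next_unique_number()
    core_id = URIRef(f"{engine.namespace.rstrip('/')}/resource/{n}-{_stamp(timestamp)}-{doc_type}")
    version_iri = generate_document_uri(engine.namespace, n, timestamp[:10], doc_type, 1)

    core_g = _register_doc_graph(engine, URIRef(f"{core_id}/graph/core-document-contents"), NamedGraphClass.CORE_DOCUMENT_CONTENTS)
    prov_g = _register_doc_graph(engine, URIRef(f"{core_id}/graph/versions-and-provenance"), NamedGraphClass.VERSIONS_AND_PROVENANCE)
    log_g = _register_doc_graph(engine, URIRef(f"{core_id}/graph/change-log"), NamedGraphClass.CHANGE_LOG)
    access_g = _register_doc_graph(engine, URIRef(f"{core_id}/graph/access-rights"), NamedGraphClass.DOCUMENT_SPECIFIC_ACCESS_RIGHTS)
    indiv_g = _register_doc_graph(engine, URIRef(f"{core_id}/graph/core-document-individuals"), NamedGraphClass.CORE_DOCUMENT_INDIVIDUALS)
    comp_g = _register_doc_graph(engine, URIRef(f"{version_iri}/graph/document-composition"), NamedGraphClass.DOCUMENT_COMPOSITION)
    asrt_g = _register_doc_graph(engine, URIRef(f"{version_iri}/graph/assertions"), NamedGraphClass.ASSERTIONS)

    record = DocumentRecord(
        core_id=core_id,
        doc_type=doc_type,
        unique_number=n,
        owner=user,
        core_contents_ng=core_g,
        provenance_ng=prov_g,
        change_log_ng=log_g,
        access_ng=access_g,
        individuals_ng=indiv_g,
    )
    version = DocumentVersion(version_iri, 1, VersionState.CURRENT_DRAFT, comp_g, asrt_g, timestamp)
    record.versions.append(version)

    for ref in (core_g, prov_g, log_g, access_g, indiv_g, comp_g, asrt_g):
        _list_graph(engine, record, ref.iri)
    store.add(core_id, RDF.type, vocab.resolve_label("document version"), core_g.iri)
    store.add(core_id, vocab.resolve_label("has unique number"), Literal(n), core_g.iri)
    store.add(core_id, vocab.resolve_label("owned by"), user, access_g.iri)
    store.add(core_id, vocab.resolve_label("has edit access right"), user, access_g.iri)

    engine.register_record(record)
    _copy_template(engine, core_id, template, comp_g.iri, indiv_g.iri)
    provenance.record_version_provenance(store, vocab, record, version, user, timestamp)
    provenance.init_change_log(store, vocab, record)
    provenance.append_status_transition(
        store, vocab, record, None, VersionState.CURRENT_DRAFT.value, timestamp
    )
    return record


def _stamp(timestamp: str) -> str:
    return datetime.date.fromisoformat(timestamp[:10]).strftime("%Y%m%d")


# ---------------------------------------------------------------------------
# the state machine


def allowed_actions(record: DocumentRecord) -> set[TransitionAction]:
    """The transition actions the life-cycle rules currently permit."""
    out: set[TransitionAction] = set()
    has_current = record.current_draft is not None
    has_saved = bool(record.versions_in(VersionState.SAVED_DRAFT))
    has_recycle = bool(record.versions_in(VersionState.RECYCLE_DRAFT))
    has_published = record.current_published is not None
    has_any_draft = bool(record.versions_in(*DRAFT_STATES))
    if has_current:
        out.update({TransitionAction.BACKUP, TransitionAction.TO_BIN, TransitionAction.PUBLISH})
    if (has_saved or has_recycle) and not has_current:
        out.add(TransitionAction.RESTORE)
    if has_published and not has_any_draft:
        out.add(TransitionAction.REVISE)
    if has_recycle:
        out.add(TransitionAction.DELETE)
    return out


def version_dependent_graphs(record: DocumentRecord, version: DocumentVersion) -> list[NamedGraphRef]:
    """The composition and assertions graphs of one version."""
    if version not in record.versions:
        raise LifecycleError(f"version {version.version_number} does not belong to {record.core_id}")
    return [ref for ref in (version.composition_ng, version.assertions_ng) if ref is not None]


def _next_version_number(record: DocumentRecord) -> int:
    return max((v.version_number for v in record.versions), default=0) + 1


def _mint_version_graphs(
    engine: "Engine", record: DocumentRecord, version_iri: URIRef, workspace: Workspace
) -> tuple[NamedGraphRef, NamedGraphRef]:
    comp = engine.store.register_graph(
        URIRef(f"{version_iri}/graph/document-composition"),
        engine.vocab.ng_class(NamedGraphClass.DOCUMENT_COMPOSITION),
        workspace,
    )
    asrt = engine.store.register_graph(
        URIRef(f"{version_iri}/graph/assertions"),
        engine.vocab.ng_class(NamedGraphClass.ASSERTIONS),
        workspace,
    )
    return comp, asrt


def _derive_version(
    engine: "Engine",
    record: DocumentRecord,
    source: DocumentVersion,
    state: VersionState,
    workspace: Workspace,
    user: URIRef,
    timestamp: str,
) -> DocumentVersion:
    """Deep-copy a version's composition/assertions graphs into a new version."""
    num = _next_version_number(record)
    version_iri = generate_document_uri(
        engine.namespace, record.unique_number, timestamp[:10], record.doc_type, num
    )
    comp, asrt = _mint_version_graphs(engine, record, version_iri, workspace)
    _copy_graph(engine.store, source.composition_ng.iri, comp.iri)
    _copy_graph(engine.store, source.assertions_ng.iri, asrt.iri)
    version = DocumentVersion(version_iri, num, state, comp, asrt, timestamp)
    record.versions.append(version)
    _list_graph(engine, record, comp.iri)
    _list_graph(engine, record, asrt.iri)
    provenance.record_version_provenance(engine.store, engine.vocab, record, version, user, timestamp)
    return version


def _erase_version(engine: "Engine", record: DocumentRecord, version: DocumentVersion) -> None:
    for ref in version_dependent_graphs(record, version):
        engine.store.unregister_graph(ref.iri)
        _unlist_graph(engine, record, ref.iri)
    record.versions.remove(version)


def _remove_record(engine: "Engine", record: DocumentRecord) -> None:
    for v in list(record.versions):
        for ref in version_dependent_graphs(record, v):
            engine.store.unregister_graph(ref.iri)
        record.versions.remove(v)
    for ref in (
        record.core_contents_ng,
        record.provenance_ng,
        record.change_log_ng,
        record.access_ng,
        record.individuals_ng,
    ):
        engine.store.unregister_graph(ref.iri)
    engine.unregister_record(record)


def apply_transition(
    engine: "Engine",
    record: DocumentRecord,
    action: TransitionAction,
    target_version: Optional[int] = None,
    user: Optional[URIRef] = None,
    timestamp: str = "",
) -> DocumentRecord:
    """Apply one life-cycle action, enforcing the transition guards; every
    applied transition appends a status node to the change-history graph."""
    store, vocab = engine.store, engine.vocab
    user = user or record.owner
    allowed = allowed_actions(record)
    if action not in allowed:
        raise TransitionRefusedError(
            f"action {action.value!r} is not permitted: allowed now: "
            f"{sorted(a.value for a in allowed)}"
        )

    if action is TransitionAction.BACKUP:
        src = record.current_draft
        _derive_version(engine, record, src, VersionState.SAVED_DRAFT, Workspace.DRAFT, user, timestamp)
        new_status = VersionState.SAVED_DRAFT.value

    elif action is TransitionAction.TO_BIN:
        if target_version is None:
            version = record.current_draft
        else:
            version = record.version(target_version)
        if version is None or version.state not in (VersionState.CURRENT_DRAFT, VersionState.SAVED_DRAFT):
            raise TransitionRefusedError("only a current or saved draft version can be moved to the bin")
        version.state = VersionState.RECYCLE_DRAFT
        new_status = VersionState.RECYCLE_DRAFT.value

    elif action is TransitionAction.RESTORE:
        if target_version is None:
            candidates = record.versions_in(VersionState.SAVED_DRAFT, VersionState.RECYCLE_DRAFT)
            version = max(candidates, key=lambda v: v.version_number)
        else:
            version = record.version(target_version)
        if version.state not in (VersionState.SAVED_DRAFT, VersionState.RECYCLE_DRAFT):
            raise TransitionRefusedError("only a saved or recycle draft version can be restored")
        version.state = VersionState.CURRENT_DRAFT
        new_status = VersionState.CURRENT_DRAFT.value

    elif action is TransitionAction.DELETE:
        if target_version is None:
            candidates = record.versions_in(VersionState.RECYCLE_DRAFT)
            version = max(candidates, key=lambda v: v.version_number)
        else:
            version = record.version(target_version)
        if version.state is not VersionState.RECYCLE_DRAFT:
            raise TransitionRefusedError("only a recycle draft version can be deleted")
        # erase all version-dependent data, keep the delete-process metadata
        for ref in version_dependent_graphs(record, version):
            for q in store.match(g=ref.iri):
                store.remove(*q)
            store.unregister_graph(ref.iri)
            _unlist_graph(engine, record, ref.iri)
        version.state = VersionState.DELETED_DRAFT
        version.composition_ng = None
        version.assertions_ng = None
        new_status = VersionState.DELETED_DRAFT.value
        provenance.append_status_transition(store, vocab, record, action.workflow_action, new_status, timestamp)
        live = [v for v in record.versions if v.state is not VersionState.DELETED_DRAFT]
        if not live:
            _remove_record(engine, record)
        return record

    elif action is TransitionAction.PUBLISH:
        src = record.current_draft
        missing = engine.unmet_required_components(record, src)
        if missing:
            raise TransitionRefusedError(
                "cannot publish: required input missing for components: "
                + ", ".join(str(m) for m in missing)
            )
        new = _derive_version(
            engine, record, src, VersionState.CURRENT_PUBLISHED, Workspace.PUBLISHED, user, timestamp
        )
        prior = [
            v
            for v in record.versions_in(VersionState.CURRENT_PUBLISHED)
            if v is not new
        ]
        for v in prior:
            v.state = VersionState.PREVIOUSLY_PUBLISHED
        # every previously published version points to the new current one
        pointer = vocab.resolve_label("points to current published version")
        for v in record.versions_in(VersionState.PREVIOUSLY_PUBLISHED):
            store.replace_object(record.provenance_ng.iri, v.version_iri, pointer, new.version_iri)
        # deletion of all saved, recycled and deleted draft versions + the source draft
        for v in list(record.versions):
            if v.state in DRAFT_STATES:
                _erase_version(engine, record, v)
            elif v.state is VersionState.DELETED_DRAFT:
                record.versions.remove(v)
        new_status = VersionState.CURRENT_PUBLISHED.value

    elif action is TransitionAction.REVISE:
        src = record.current_published
        _derive_version(engine, record, src, VersionState.CURRENT_DRAFT, Workspace.DRAFT, user, timestamp)
        new_status = VersionState.CURRENT_DRAFT.value

    else:  # pragma: no cover
        raise TransitionRefusedError(f"unknown action {action}")

    provenance.append_status_transition(store, vocab, record, action.workflow_action, new_status, timestamp)
    return record
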