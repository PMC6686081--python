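"""The engine facade: one quad store, one vocabulary, one source model.

An :class:`Engine` owns the workspace-partitioned store, interprets loaded
source-code ontologies and exposes the user-facing operations: create
documents, submit form input, drive the life cycle, compose views and read
histories.  Timestamps are always injected by the caller (UTC ISO 8601);
the engine never reads the wall clock itself, which keeps every run
reproducible.
"""

from __future__ import annotations

from typing import Optional, Union

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import RDF

from . import interpreter, lifecycle, provenance, view
from .source_loader import SourceModel, load_source_ontology
from .store import ANY, NamedGraphRef, QuadStore, Workspace, create_store
from .vocabulary import NamedGraphClass, Vocabulary, WorkflowAction
from .source_loader import DEFAULT_NG_BINDINGS


class EngineError(Exception):
    pass


class Engine:
    def __init__(
        self,
        namespace: str = "https://semcms.dev",
        vocab: Optional[Vocabulary] = None,
        store: Optional[QuadStore] = None,
    ) -> None:
        self.namespace = namespace.rstrip("/")
        self.vocab = vocab or Vocabulary()
        self.store = store or create_store()
        self.model = SourceModel()
        self.records: dict[URIRef, lifecycle.DocumentRecord] = {}
        self.sessions: dict[str, URIRef] = {}
        self._admin_iri = URIRef(f"{self.namespace}/admin/registry")
        if self._admin_iri not in self.store.graph_registry:
            self.store.register_graph(
                self._admin_iri, self.vocab.resolve_label("admin registry named graph"), Workspace.ADMIN
            )

    # -- sources -----------------------------------------------------------

    def load_ontology(self, source: Union[str, Graph], format: Optional[str] = None) -> SourceModel:
        """Load a source-code ontology and merge it into the engine's model."""
        model = load_source_ontology(source, self.vocab, format=format)
        self.model.merge(model)
        return model

    def ng_workspace(self, ngc: NamedGraphClass) -> Workspace:
        return self.model.ng_class_bindings.get(ngc, DEFAULT_NG_BINDINGS[ngc])

    # -- counters and sessions ----------------------------------------------

    def next_unique_number(self) -> int:
        pred = self.vocab.resolve_label("next unique number")
        current = self.store.value(self._admin_iri, pred, self._admin_iri)
        n = int(str(current)) if current is not None else 1
        self.store.replace_object(self._admin_iri, self._admin_iri, pred, Literal(n + 1))
        return n

    def open_session(self, session_id: str, user: URIRef) -> str:
        self.sessions[session_id] = user
        return session_id

    def user_contributions_graph(self, user: URIRef) -> URIRef:
        iri = URIRef(str(user).rstrip("/") + "/contributions")
        if iri not in self.store.graph_registry:
            self.store.register_graph(
                iri, self.vocab.resolve_label("user contributions named graph"), Workspace.ADMIN
            )
        return iri

    # -- records -----------------------------------------------------------

    def register_record(self, record: lifecycle.DocumentRecord) -> None:
        self.records[record.core_id] = record

    def unregister_record(self, record: lifecycle.DocumentRecord) -> None:
        self.records.pop(record.core_id, None)

    def get_record(self, core_id: Union[str, URIRef]) -> lifecycle.DocumentRecord:
        try:
            return self.records[URIRef(core_id)]
        except KeyError:
            raise EngineError(f"unknown document {core_id}") from None

    def create_document(self, doc_type: str, user: URIRef, timestamp: str) -> lifecycle.DocumentRecord:
        return lifecycle.create_document(self, doc_type, user, timestamp)

    def apply_transition(
        self,
        record: lifecycle.DocumentRecord,
        action: lifecycle.TransitionAction,
        target_version: Optional[int] = None,
        user: Optional[URIRef] = None,
        timestamp: str = "",
    ) -> lifecycle.DocumentRecord:
        return lifecycle.apply_transition(self, record, action, target_version, user, timestamp)

    # -- access rights -------------------------------------------------------

    def has_edit_right(self, record: lifecycle.DocumentRecord, user: URIRef) -> bool:
        pred = self.vocab.resolve_label("has edit access right")
        return bool(self.store.match(record.core_id, pred, user, record.access_ng.iri))

    def grant_edit_right(self, record: lifecycle.DocumentRecord, user: URIRef) -> None:
        pred = self.vocab.resolve_label("has edit access right")
        if not self.store.match(record.core_id, pred, user, record.access_ng.iri):
            self.store.add(record.core_id, pred, user, record.access_ng.iri)

    # -- document graphs and individuals -------------------------------------

    def document_graph(
        self,
        record: lifecycle.DocumentRecord,
        version: Optional[lifecycle.DocumentVersion],
        ngc: NamedGraphClass,
    ) -> NamedGraphRef:
        """This document's specific named-graph individual of a graph class."""
        version_scoped = {
            NamedGraphClass.DOCUMENT_COMPOSITION: "composition_ng",
            NamedGraphClass.ASSERTIONS: "assertions_ng",
        }
        if ngc in version_scoped:
            if version is None:
                raise EngineError(f"graph class {ngc} is version-dependent")
            ref = getattr(version, version_scoped[ngc])
            if ref is None:
                raise EngineError(f"version {version.version_number} has no {ngc.value}")
            return ref
        mapping = {
            NamedGraphClass.CORE_DOCUMENT_CONTENTS: record.core_contents_ng,
            NamedGraphClass.VERSIONS_AND_PROVENANCE: record.provenance_ng,
            NamedGraphClass.CHANGE_LOG: record.change_log_ng,
            NamedGraphClass.DOCUMENT_SPECIFIC_ACCESS_RIGHTS: record.access_ng,
            NamedGraphClass.CORE_DOCUMENT_INDIVIDUALS: record.individuals_ng,
        }
        try:
            return mapping[ngc]
        except KeyError:
            raise EngineError(f"no graph of class {ngc} for document {record.core_id}") from None

    def document_individual(
        self,
        record: Optional[lifecycle.DocumentRecord],
        class_iri: URIRef,
        mint: bool = False,
        indiv_g: Optional[URIRef] = None,
        core_id: Optional[URIRef] = None,
    ) -> URIRef:
        """This document's specific individual of ``class_iri``, looked up
        in (and, with ``mint``, added to) the core-document-individuals
        graph."""
        g = indiv_g if indiv_g is not None else record.individuals_ng.iri
        base = core_id if core_id is not None else record.core_id
        hits = self.store.match(ANY, RDF.type, class_iri, g)
        if hits:
            return hits[0][0]
        if not mint:
            raise EngineError(f"document has no individual of class {class_iri}")
        n = len(self.store.match(ANY, RDF.type, ANY, g)) + 1
        inst = URIRef(f"{base}/individual/{n}")
        self.store.add(inst, RDF.type, class_iri, g)
        return inst

    # -- user input -----------------------------------------------------------

    def submit_input(
        self,
        record: lifecycle.DocumentRecord,
        component_instance: URIRef,
        raw_input: str,
        user: URIRef,
        session: str,
        timestamp: str,
    ) -> interpreter.EngineResponse:
        """Run the execution program of the addressed entry component for
        one raw input event against the current draft version."""
        version = record.current_draft
        if version is None:
            raise EngineError("document has no current draft version to edit")
        cls = self.store.value(component_instance, RDF.type, version.composition_ng.iri)
        if cls is None:
            raise EngineError(
                f"component {component_instance} is not part of the current draft's composition"
            )
        ctx = interpreter.ExecutionContext(
            record=record,
            version=version,
            component_instance=component_instance,
            component_class=cls,
            user=user,
            session=session,
            raw_input=raw_input,
            timestamp=timestamp,
        )
        return interpreter.run_trigger(self, ctx)

    # -- views and histories ---------------------------------------------------

    def compose_view(
        self, record: lifecycle.DocumentRecord, version: Optional[lifecycle.DocumentVersion] = None
    ) -> view.ViewNode:
        v = version or record.current_draft or record.current_published
        if v is None:
            raise EngineError("document has no viewable version")
        return view.compose_view(self, record, v)

    def unmet_required_components(
        self, record: lifecycle.DocumentRecord, version: lifecycle.DocumentVersion
    ) -> list[URIRef]:
        tree = view.compose_view(self, record, version)
        return [n.component for n in tree.walk() if n.required_but_empty]

    def change_history(self, record: lifecycle.DocumentRecord):
        return provenance.get_change_history(self.store, self.vocab, record)

    def provenance_chain(self, record: lifecycle.DocumentRecord):
        return provenance.provenance_chain(self.store, self.vocab, record)

    def replay_history(
        self,
        entries: list[provenance.ChangeLogEntry],
        record: lifecycle.DocumentRecord,
    ) -> None:
        """Re-run each logged editing step (field, value, user, session,
        timestamp) through the interpreter against this engine's document."""
        for e in entries:
            resp = self.submit_input(
                record, e.input_field, str(e.new_value), e.user, e.session, e.timestamp
            )
            if resp.status != "ok":
                raise EngineError(f"replay failed at {e.input_field}: {resp.status}")

    # -- export -----------------------------------------------------------------

    def export(self, format: str = "trig") -> str:
        return self.store.serialize(format)

    def query_published(self, patterns, graphs=None):
        return self.store.query_published(patterns, graphs)
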