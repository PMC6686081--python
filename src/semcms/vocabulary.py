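"""Registry of the command, variable and value IRIs the engine interprets.

Source-code ontologies drive the engine through annotation properties
("commands"), ontology individuals acting as runtime placeholders
("variables") and enumerated values (IF operations, workflow actions,
input-control types, named-graph classes).  This module mints stable IRIs
for the interpreted subset under a configurable base namespace and keeps a
bijective label <-> IRI registry.

Labels are matched exactly as printed in the source ontologies, including
bracketed suffixes like '[input_B]'; the space variant '[input M]' is
accepted as an alias for '[input_M]'.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass

from rdflib import Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .store import Workspace

DEFAULT_BASE = "https://semcms.dev/vocab/"


class VocabularyError(KeyError):
    pass


def _slug(label: str) -> str:
    s = re.sub(r"[^A-Za-z0-9]+", "-", label).strip("-")
    return s or "term"


@dataclass(frozen=True)
class CommandDescriptor:
    iri: URIRef
    label: str
    arity: str  # value | resource | label


@dataclass(frozen=True)
class VariableDescriptor:
    iri: URIRef
    label: str


class IfOperation(enum.Enum):
    SOME_INPUT_LARGER_THAN_TARGET = "SPrO_IF_OPERATION: SOME input larger than target"
    SOME_INPUT_SMALLER_THAN_TARGET = "SPrO_IF_OPERATION: SOME input smaller than target"


class WorkflowAction(enum.Enum):
    EDIT = "edit"
    CREATE = "create"
    BACKUP = "backup"
    TO_BIN = "to_bin"
    RESTORE = "restore"
    DELETE = "delete"
    PUBLISH = "publish"
    REVISE = "revise"

    @property
    def label(self) -> str:
        return "SOCCOMAS_BASIC_WORKFLOW_ACTION: " + self.value.replace("_", " ")


class NamedGraphClass(enum.Enum):
    """The eight named-graph classes of a document's graph network."""

    CORE_DOCUMENT_CONTENTS = "core document contents named graph"
    DOCUMENT_VERSION_CONTENTS = "document version contents named graph"
    VERSIONS_AND_PROVENANCE = "versions and provenance named graph"
    CHANGE_LOG = "change-log named graph"
    DOCUMENT_SPECIFIC_ACCESS_RIGHTS = "document-specific access-rights named graph"
    CORE_DOCUMENT_INDIVIDUALS = "core document individuals named graph"
    DOCUMENT_COMPOSITION = "document-composition named graph"
    ASSERTIONS = "assertions named graph"


class InputControlType(enum.Enum):
    BOOLEAN = "Boolean"
    CLICK = "click"
    PHONE_NUMBER = "phone number"
    EMAIL_ADDRESS = "email address"
    COMPOSITE_LITERAL = "composite literal"
    GEOJSON_STRING = "GeoJSON string"
    LITERAL = "literal"
    DATE = "date"
    DATE_TIME = "date time"
    DECIMAL_DEGREE = "decimal degree"
    FLOAT = "float"
    FLOAT_PH = "float pH"
    FLOAT_PERCENTAGE = "float percentage"
    GEO_LATITUDE = "geo-coordinate decimal latitude"
    GEO_LONGITUDE = "geo-coordinate decimal longitude"
    INTEGER_PERCENTAGE = "integer percentage"
    POSITIVE_INTEGER = "positive integer"

    @property
    def label(self) -> str:
        return "INPUT_CONTROL: " + self.value


# (label, arity) of every command the interpreter understands
_COMMANDS: list[tuple[str, str]] = [
    ("entry component of", "resource"),
    ("has entry component", "resource"),
    ("has position in entry component", "value"),
    ("has GUI representation", "resource"),
    ("required input [BOOLEAN]", "value"),
    ("execution step trigger", "label"),
    ("execution step: search triple store", "label"),
    ("execution step: if-then-else statement", "label"),
    ("execution step: decision dialogue", "label"),
    ("execution step: update triple statement(s)", "label"),
    ("execution step: trigger workflow action", "label"),
    ("subject", "resource"),
    ("property", "resource"),
    ("object", "resource"),
    ("subject (this document’s specific individual of)", "resource"),
    ("search target", "resource"),
    ("search target defines SPrO variable", "resource"),
    ("load from/save to/update in named graph (this document’s specific individual of)", "resource"),
    ("named graph belongs to workspace", "resource"),
    ("update with resource/value", "resource"),
    ("has IF input value", "resource"),
    ("has IF target value", "resource"),
    ("has IF operation", "resource"),
    ("then:", "value"),
    ("application error message", "value"),
    ("end action operation", "resource"),
    ("has GUI input type", "resource"),
    ("input value/resource defines SPrO variable resource", "resource"),
    ("requirement for triggering the execution step", "resource"),
    ("with information text", "value"),
    ("tooltip text", "value"),
    ("triggers workflow action", "resource"),
    ("has associated instance resource [input_A]", "resource"),
    ("has associated instance resource [input_B]", "resource"),
    ("has associated instance resource [input_M]", "resource"),
    # engine-plumbing commands used by the basic ontology and the stores
    ("entry form template of document type", "value"),
    ("has user/GUI input [value_B]", "value"),
    ("lists named graph", "resource"),
]

_VARIABLES: list[str] = [
    "SPrO_VARIABLE: empty",
    "SPrO_VARIABLE:?",
    "SPrO_VARIABLE: this entry component",
    "SPrO_VARIABLE: subject",
    "SPrO_VARIABLE: object",
    "SPrO_VARIABLE: to be updated",
    "SPrO_VARIABLE: user/GUI input [input_B]",
    "SPrO_VARIABLE: associated instance resource [input_A]",
    "SPrO_VARIABLE: associated instance resource [input_M]",
    "SPrO_VARIABLE: edit document-access-right for this document",
]

_OPERATIONS: list[str] = [
    "SPrO_OPERATION: ERROR end action",
]

#: provenance / change-log surrogate predicates (exportable to pav/dcterms/
#: ti/tvc equivalents through an alias table)
_PROV_PREDICATES: list[str] = [
    "previous version",
    "points to current published version",
    "created by",
    "created on",
    "contributed by",
    "interval start",
    "interval end",
    "previous entry state",
    "has logged change",
    "logged on",
    "logged by user",
    "logged in session",
    "changed input field",
    "new value",
    "has document status",
    "status transition process",
    "previous document status",
    "has edit access right",
    "owned by",
    "has unique number",
    "has version number",
    "next unique number",
    "contributed to document",
    # structural classes for the tracking graphs
    "entry state in time",
    "logged change",
    "document status in time",
    "document version",
    "admin registry named graph",
]

_STATUS_LABELS: list[str] = [
    "current draft version",
    "saved draft version",
    "recycle draft version",
    "deleted draft version",
    "current published version",
    "previously published version",
]


class Vocabulary:
    """Bijective label <-> IRI registry for the interpreted vocabulary."""

    def __init__(self, base: str = DEFAULT_BASE) -> None:
        self.base = base
        self.ns = Namespace(base)
        self._by_label: dict[str, URIRef] = {}
        self._by_iri: dict[URIRef, str] = {}
        self._aliases: dict[str, str] = {}
        self.commands: dict[str, CommandDescriptor] = {}
        self.variables: dict[str, VariableDescriptor] = {}

        for label, arity in _COMMANDS:
            iri = self._register(label)
            self.commands[label] = CommandDescriptor(iri, label, arity)
        for label in _VARIABLES:
            self.variables[label] = VariableDescriptor(self._register(label), label)
        for label in _OPERATIONS + _PROV_PREDICATES + _STATUS_LABELS:
            self._register(label)
        for op in IfOperation:
            self._register(op.value)
        for action in WorkflowAction:
            self._register(action.label)
        for ngc in NamedGraphClass:
            self._register(ngc.value)
        for ctl in InputControlType:
            self._register(ctl.label)
        for ws in Workspace:
            self._register("WORKSPACE_BASIC: " + ws.value.replace("_", " ") + " workspace")
        # admin-workspace plumbing class for per-user contribution graphs
        self._register("user contributions named graph")

        # spacing aliases: '[input M]' form for every '[input_X]' label
        for label in list(self._by_label):
            if "[input_" in label:
                self._aliases[label.replace("[input_", "[input ")] = label

    # -- registry ----------------------------------------------------------

    def _register(self, label: str) -> URIRef:
        if label in self._by_label:
            raise VocabularyError(f"duplicate vocabulary label: {label!r}")
        iri = self.ns[_slug(label)]
        if iri in self._by_iri:
            raise VocabularyError(f"IRI collision for label {label!r}: {iri}")
        self._by_label[label] = iri
        self._by_iri[iri] = label
        return iri

    def resolve_label(self, label: str) -> URIRef:
        label = self._aliases.get(label, label)
        try:
            return self._by_label[label]
        except KeyError:
            raise VocabularyError(f"unknown vocabulary label: {label!r}") from None

    def label_of(self, iri: URIRef) -> str:
        try:
            return self._by_iri[iri]
        except KeyError:
            raise VocabularyError(f"IRI not in vocabulary: {iri}") from None

    def __contains__(self, label: str) -> bool:
        return self._aliases.get(label, label) in self._by_label

    def __len__(self) -> int:
        return len(self._by_label)

    # -- convenience accessors --------------------------------------------

    @property
    def variables_by_iri(self) -> dict[URIRef, VariableDescriptor]:
        return {d.iri: d for d in self.variables.values()}

    def cmd(self, label: str) -> URIRef:
        """IRI of a command (annotation property)."""
        label = self._aliases.get(label, label)
        if label not in self.commands:
            raise VocabularyError(f"not a command label: {label!r}")
        return self.commands[label].iri

    def var(self, label: str) -> URIRef:
        if label not in self.variables:
            raise VocabularyError(f"not a variable label: {label!r}")
        return self.variables[label].iri

    def ng_class(self, ngc: NamedGraphClass) -> URIRef:
        return self._by_label[ngc.value]

    def ng_class_of(self, iri: URIRef) -> NamedGraphClass:
        label = self.label_of(iri)
        for ngc in NamedGraphClass:
            if ngc.value == label:
                return ngc
        raise VocabularyError(f"not a named-graph class: {iri}")

    def workflow_action(self, action: WorkflowAction) -> URIRef:
        return self._by_label[action.label]

    def workflow_action_of(self, iri: URIRef) -> WorkflowAction:
        label = self.label_of(iri)
        for action in WorkflowAction:
            if action.label == label:
                return action
        raise VocabularyError(f"not a workflow action: {iri}")

    def if_operation(self, op: IfOperation) -> URIRef:
        return self._by_label[op.value]

    def if_operation_of(self, iri: URIRef) -> IfOperation:
        label = self.label_of(iri)
        for op in IfOperation:
            if op.value == label:
                return op
        raise VocabularyError(f"not an IF operation: {iri}")

    def input_control(self, ctl: InputControlType) -> URIRef:
        return self._by_label[ctl.label]

    def input_control_of(self, iri: URIRef) -> InputControlType:
        label = self.label_of(iri)
        for ctl in InputControlType:
            if ctl.label == label:
                return ctl
        raise VocabularyError(f"not an input control: {iri}")

    def workspace_term(self, ws: Workspace) -> URIRef:
        return self._by_label["WORKSPACE_BASIC: " + ws.value.replace("_", " ") + " workspace"]

    def workspace_of(self, iri: URIRef) -> Workspace:
        label = self.label_of(iri)
        for ws in Workspace:
            if label == "WORKSPACE_BASIC: " + ws.value.replace("_", " ") + " workspace":
                return ws
        raise VocabularyError(f"not a workspace term: {iri}")

    def status_term(self, status_label: str) -> URIRef:
        if status_label not in _STATUS_LABELS:
            raise VocabularyError(f"not a status label: {status_label!r}")
        return self._by_label[status_label]

    def list_input_controls(self) -> list[InputControlType]:
        """The seventeen input-control types the engine validates."""
        return list(InputControlType)

    # -- export ------------------------------------------------------------

    def to_graph(self) -> Graph:
        """The vocabulary as an RDF graph, importable by source ontologies."""
        g = Graph()
        g.bind("vocab", self.ns)
        for label, desc in self.commands.items():
            g.add((desc.iri, RDF.type, OWL.AnnotationProperty))
            g.add((desc.iri, RDFS.label, Literal(label)))
        for label, desc in self.variables.items():
            g.add((desc.iri, RDF.type, OWL.NamedIndividual))
            g.add((desc.iri, RDFS.label, Literal(label)))
        for label, iri in self._by_label.items():
            if label not in self.commands and label not in self.variables:
                g.add((iri, RDFS.label, Literal(label)))
        return g

    def export_turtle(self) -> str:
        return self.to_graph().serialize(format="turtle")


#: module-level default registry; engines may mint their own base
VOCAB = Vocabulary()
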