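"""Parse a source-code ontology into form templates and step programs.

A source-code ontology describes an entry form declaratively: ontology
instances are entry components arranged in a nested hierarchy ('entry
component of' links plus 'has position in entry component'), and the class
each component instantiates carries its GUI representation, its required
flag and a sequentially ordered program of execution steps.  Subcommands of
a class annotation are read either from OWL axiom annotations on it or, in
a flattened encoding, from a dedicated step node carrying the parameters as
direct properties.

Loading is insensitive to RDF statement order; everything is keyed by IRI.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional, Union

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .store import Term, Workspace
from .vocabulary import NamedGraphClass, Vocabulary, VocabularyError


class SourceLoadError(Exception):
    pass


class StepLabelError(ValueError):
    pass


class StepType(enum.Enum):
    TRIGGER = "execution step trigger"
    SEARCH_TRIPLE_STORE = "execution step: search triple store"
    IF_THEN_ELSE = "execution step: if-then-else statement"
    DECISION_DIALOGUE = "execution step: decision dialogue"
    UPDATE_TRIPLES = "execution step: update triple statement(s)"
    TRIGGER_WORKFLOW_ACTION = "execution step: trigger workflow action"


#: mandatory subcommand labels per step type
MANDATORY_PARAMS: dict[StepType, tuple[str, ...]] = {
    StepType.TRIGGER: ("has GUI input type",),
    StepType.SEARCH_TRIPLE_STORE: ("subject", "property", "object", "search target"),
    StepType.IF_THEN_ELSE: ("has IF input value", "has IF target value", "has IF operation", "then:"),
    StepType.DECISION_DIALOGUE: ("end action operation",),
    StepType.UPDATE_TRIPLES: ("property", "object", "update with resource/value"),
    StepType.TRIGGER_WORKFLOW_ACTION: ("triggers workflow action",),
}

_LABEL_RE = re.compile(r"^(\d+)([A-Z]?)$")


def step_key(label: str) -> tuple[int, str]:
    """Sort key for a step label: numeric major, letter minor ('0' < '1A' < '2A' < '2B')."""
    m = _LABEL_RE.match(label)
    if not m:
        raise StepLabelError(f"malformed execution step label: {label!r}")
    return (int(m.group(1)), m.group(2))


def step_order(label_a: str, label_b: str) -> int:
    """-1, 0 or 1 as ``label_a`` sorts before, equal to or after ``label_b``."""
    ka, kb = step_key(label_a), step_key(label_b)
    return (ka > kb) - (ka < kb)


@dataclass
class ExecutionStepSpec:
    label: str
    step_type: StepType
    params: dict[URIRef, Term]  # command IRI -> value/resource/variable

    def param(self, vocab: Vocabulary, label: str) -> Optional[Term]:
        return self.params.get(vocab.cmd(label))


@dataclass
class ExecutionProgram:
    component_class: URIRef
    steps: list[ExecutionStepSpec] = field(default_factory=list)

    def sort(self) -> None:
        self.steps.sort(key=lambda s: step_key(s.label))

    def step(self, label: str) -> Optional[ExecutionStepSpec]:
        for s in self.steps:
            if s.label == label:
                return s
        return None

    def next_label(self, label: str) -> Optional[str]:
        labels = [s.label for s in self.steps]
        i = labels.index(label)
        return labels[i + 1] if i + 1 < len(labels) else None


@dataclass
class EntryComponentTemplate:
    instance_iri: URIRef
    class_iri: URIRef
    parent: Optional[URIRef] = None
    position: int = 1
    gui_representation: Optional[str] = None  # CSS-class token
    tooltip: Optional[str] = None
    info_text: Optional[str] = None
    required: bool = False
    associated_slots: dict[str, Term] = field(default_factory=dict)  # slot label -> initial value
    label: Optional[str] = None
    children: list["EntryComponentTemplate"] = field(default_factory=list)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # 'error' | 'warning'
    message: str
    context: str = ""


@dataclass
class SourceModel:
    templates: dict[str, EntryComponentTemplate] = field(default_factory=dict)  # doc type -> root
    programs: dict[URIRef, ExecutionProgram] = field(default_factory=dict)  # component class -> program
    ng_class_bindings: dict[NamedGraphClass, Workspace] = field(default_factory=dict)
    class_annotations: dict[URIRef, dict] = field(default_factory=dict)
    load_diagnostics: list[Diagnostic] = field(default_factory=list)

    def merge(self, other: "SourceModel") -> None:
        self.templates.update(other.templates)
        self.programs.update(other.programs)
        self.ng_class_bindings.update(other.ng_class_bindings)
        self.class_annotations.update(other.class_annotations)
        self.load_diagnostics.extend(other.load_diagnostics)


# default Fig-6-style workspace binding for the eight graph classes
DEFAULT_NG_BINDINGS: dict[NamedGraphClass, Workspace] = {
    NamedGraphClass.CORE_DOCUMENT_CONTENTS: Workspace.CORE,
    NamedGraphClass.VERSIONS_AND_PROVENANCE: Workspace.CORE,
    NamedGraphClass.CHANGE_LOG: Workspace.CORE,
    NamedGraphClass.DOCUMENT_SPECIFIC_ACCESS_RIGHTS: Workspace.CORE,
    NamedGraphClass.CORE_DOCUMENT_INDIVIDUALS: Workspace.CORE,
    NamedGraphClass.DOCUMENT_VERSION_CONTENTS: Workspace.CORE,
    NamedGraphClass.DOCUMENT_COMPOSITION: Workspace.DRAFT,
    NamedGraphClass.ASSERTIONS: Workspace.DRAFT,
}

_STEP_CMDS = {st.value: st for st in StepType}
_OWL_AXIOM_PROPS = (OWL.annotatedSource, OWL.annotatedProperty, OWL.annotatedTarget)


def _axiom_params(graph: Graph, source: Term, prop: URIRef, target: Term) -> dict[URIRef, Term]:
    """Subcommand map read from OWL axiom annotations on (source, prop, target)."""
    params: dict[URIRef, Term] = {}
    for ax in graph.subjects(OWL.annotatedSource, source):
        if (ax, RDF.type, OWL.Axiom) not in graph:
            continue
        if (ax, OWL.annotatedProperty, prop) not in graph or (ax, OWL.annotatedTarget, target) not in graph:
            continue
        for p, o in graph.predicate_objects(ax):
            if p in _OWL_AXIOM_PROPS or p == RDF.type:
                continue
            params[p] = o
    return params


def _gui_token(graph: Graph, value: Term) -> Optional[str]:
    if isinstance(value, Literal):
        return str(value)
    label = graph.value(value, RDFS.label)
    if label is None:
        return str(value)
    text = str(label)
    if ":" in text and text.startswith("GUI_COMPONENT"):
        return text.split(":", 1)[1].strip()
    return text


def load_source_ontology(
    source: Union[str, Graph],
    vocab: Vocabulary,
    format: Optional[str] = None,
    strict: bool = True,
) -> SourceModel:
    """Extract form templates, class annotations and step programs.

    ``source`` is a file path, serialized RDF text, or an rdflib Graph
    (Turtle and RDF/XML accepted).  With ``strict`` (default), a step
    missing one of its mandatory parameters raises :class:`SourceLoadError`
    naming the component class and step label; otherwise the problem is
    recorded as a load diagnostic and loading continues.
    """
    if isinstance(source, Graph):
        graph = source
    else:
        graph = Graph()
        if "\n" in source or source.lstrip().startswith(("@prefix", "<?xml", "<rdf", "PREFIX")):
            _parse_any(graph, data=source, format=format)
        else:
            _parse_any(graph, location=source, format=format)

    model = SourceModel()
    cmd = vocab.cmd

    # ---- named-graph class -> workspace bindings
    for ngc in NamedGraphClass:
        ws_term = graph.value(vocab.ng_class(ngc), cmd("named graph belongs to workspace"))
        if ws_term is not None:
            model.ng_class_bindings[ngc] = vocab.workspace_of(ws_term)

    # ---- entry component instances
    parent_of: dict[URIRef, URIRef] = {}
    instances: set[URIRef] = set()
    for s, o in graph.subject_objects(cmd("entry component of")):
        parent_of[s] = o
        instances.update((s, o))
    for s, o in graph.subject_objects(cmd("has entry component")):
        parent_of[o] = s
        instances.update((s, o))
    for s in graph.subjects(cmd("has position in entry component"), None):
        instances.add(s)
    roots = {s for s in graph.subjects(cmd("entry form template of document type"), None)}
    instances |= roots

    components: dict[URIRef, EntryComponentTemplate] = {}
    slot_cmds = {
        lbl: vocab.cmd(lbl)
        for lbl in vocab.commands
        if lbl.startswith("has associated instance resource")
    }
    for inst in instances:
        cls = graph.value(inst, RDF.type) or RDFS.Resource
        pos_lit = graph.value(inst, cmd("has position in entry component"))
        try:
            pos = int(str(pos_lit)) if pos_lit is not None else 1
        except ValueError:
            pos = 1
            model.load_diagnostics.append(
                Diagnostic("error", f"non-integer position {pos_lit!r}", str(inst))
            )
        slots = {}
        for lbl, p in slot_cmds.items():
            v = graph.value(inst, p)
            if v is not None:
                slots[lbl] = v
        lab = graph.value(inst, RDFS.label)
        components[inst] = EntryComponentTemplate(
            instance_iri=inst,
            class_iri=cls,
            parent=parent_of.get(inst),
            position=pos,
            associated_slots=slots,
            label=str(lab) if lab is not None else None,
        )

    # ---- class-level annotations (GUI representation, required, programs)
    classes = {c.class_iri for c in components.values()}
    for cls in sorted(classes, key=str):
        ann: dict = {"gui_representation": None, "tooltip": None, "info_text": None, "required": False}
        gui_val = graph.value(cls, cmd("has GUI representation"))
        if gui_val is not None:
            ann["gui_representation"] = _gui_token(graph, gui_val)
            sub = _axiom_params(graph, cls, cmd("has GUI representation"), gui_val)
            tip = sub.get(cmd("tooltip text")) or graph.value(cls, cmd("tooltip text"))
            info = sub.get(cmd("with information text")) or graph.value(cls, cmd("with information text"))
            ann["tooltip"] = str(tip) if tip is not None else None
            ann["info_text"] = str(info) if info is not None else None
        else:
            tip = graph.value(cls, cmd("tooltip text"))
            info = graph.value(cls, cmd("with information text"))
            ann["tooltip"] = str(tip) if tip is not None else None
            ann["info_text"] = str(info) if info is not None else None
        req = graph.value(cls, cmd("required input [BOOLEAN]"))
        ann["required"] = str(req).lower() == "true" if req is not None else False
        model.class_annotations[cls] = ann

        steps: list[ExecutionStepSpec] = []
        for step_label_cmd, step_type in _STEP_CMDS.items():
            prop = cmd(step_label_cmd)
            for target in graph.objects(cls, prop):
                if isinstance(target, Literal):
                    label = str(target)
                    params = _axiom_params(graph, cls, prop, target)
                else:
                    # flattened encoding: dedicated step node
                    lab = graph.value(target, RDFS.label)
                    label = str(lab) if lab is not None else ""
                    params = {
                        p: o
                        for p, o in graph.predicate_objects(target)
                        if p not in (RDF.type, RDFS.label)
                    }
                try:
                    step_key(label)
                except StepLabelError:
                    model.load_diagnostics.append(
                        Diagnostic("error", f"malformed step label {label!r}", str(cls))
                    )
                    continue
                missing = [
                    m for m in MANDATORY_PARAMS[step_type] if cmd(m) not in params
                ]
                if missing:
                    msg = (
                        f"step {label!r} of component class {cls} is missing "
                        f"mandatory parameter(s): {', '.join(missing)}"
                    )
                    if strict:
                        raise SourceLoadError(msg)
                    model.load_diagnostics.append(Diagnostic("error", msg, str(cls)))
                steps.append(ExecutionStepSpec(label, step_type, params))
        if steps:
            prog = ExecutionProgram(cls, steps)
            prog.sort()
            model.programs[cls] = prog

    # ---- assemble template trees
    for c in components.values():
        if c.parent is not None and c.parent in components:
            components[c.parent].children.append(c)
        ann = model.class_annotations.get(c.class_iri, {})
        c.gui_representation = ann.get("gui_representation")
        c.tooltip = ann.get("tooltip")
        c.info_text = ann.get("info_text")
        c.required = bool(ann.get("required"))
    for c in components.values():
        c.children.sort(key=lambda ch: (ch.position, str(ch.instance_iri)))

    for root in sorted(roots, key=str):
        doc_type = str(graph.value(root, cmd("entry form template of document type")))
        model.templates[doc_type] = components[root]

    return model


def _parse_any(graph: Graph, **kw) -> None:
    fmt = kw.pop("format", None)
    if fmt:
        graph.parse(format=fmt, **kw)
        return
    for candidate in ("turtle", "xml"):
        try:
            graph.parse(format=candidate, **kw)
            return
        except Exception:
            continue
    raise SourceLoadError("input does not parse as Turtle or RDF/XML")


def extract_form_template(model: SourceModel, doc_type: str) -> EntryComponentTemplate:
    """Return the component tree for a document type, validated for cycles
    and ordered by sibling position (ties broken by IRI sort)."""
    if doc_type not in model.templates:
        raise SourceLoadError(f"no entry form template for document type {doc_type!r}")
    root = model.templates[doc_type]
    seen: set[URIRef] = set()
    stack = [root]
    while stack:
        node = stack.pop()
        if node.instance_iri in seen:
            raise SourceLoadError(f"cycle in entry-component hierarchy at {node.instance_iri}")
        seen.add(node.instance_iri)
        stack.extend(node.children)
    return root


def validate_source(model: SourceModel, vocab: Vocabulary) -> list[Diagnostic]:
    """Static diagnostics over a loaded source model.

    Reports missing mandatory step parameters, dangling 'then:' targets,
    unknown IF operations and input controls, unreachable steps, duplicate
    sibling positions (warning) and required components without a trigger
    program.  Never raises: everything comes back severity-tagged.
    """
    diags: list[Diagnostic] = list(model.load_diagnostics)
    cmd = vocab.cmd

    template_classes: set[URIRef] = set()
    for doc_type, root in model.templates.items():
        for node in root.walk():
            template_classes.add(node.class_iri)
            positions: dict[int, list[str]] = {}
            for ch in node.children:
                positions.setdefault(ch.position, []).append(str(ch.instance_iri))
            for pos, insts in positions.items():
                if len(insts) > 1:
                    diags.append(
                        Diagnostic(
                            "warning",
                            f"duplicate sibling position {pos} under {node.instance_iri} "
                            f"(tie broken by IRI sort)",
                            doc_type,
                        )
                    )
            if node.required and node.class_iri not in model.programs:
                diags.append(
                    Diagnostic(
                        "error",
                        f"component class {node.class_iri} is required but has no trigger program",
                        doc_type,
                    )
                )

    for cls, prog in model.programs.items():
        ctx = str(cls)
        labels = [s.label for s in prog.steps]
        triggers = [s for s in prog.steps if s.step_type is StepType.TRIGGER]
        if len(triggers) != 1 or triggers[0].label != "0":
            diags.append(
                Diagnostic("error", "program must have exactly one trigger step labeled '0'", ctx)
            )
        for s in prog.steps:
            for m in MANDATORY_PARAMS[s.step_type]:
                if cmd(m) not in s.params:
                    diags.append(
                        Diagnostic(
                            "error",
                            f"step {s.label!r} missing mandatory parameter {m!r}",
                            ctx,
                        )
                    )
            if s.step_type is StepType.IF_THEN_ELSE:
                target = s.params.get(cmd("then:"))
                if target is not None and str(target) not in labels:
                    diags.append(
                        Diagnostic("error", f"step {s.label!r}: dangling 'then:' target {target}", ctx)
                    )
                op = s.params.get(cmd("has IF operation"))
                if op is not None:
                    try:
                        vocab.if_operation_of(op)
                    except VocabularyError:
                        diags.append(Diagnostic("error", f"unknown IF operation {op}", ctx))
            if s.step_type is StepType.TRIGGER:
                ctl = s.params.get(cmd("has GUI input type"))
                if ctl is not None:
                    try:
                        vocab.input_control_of(ctl)
                    except VocabularyError:
                        diags.append(Diagnostic("error", f"unknown input control {ctl}", ctx))
            if s.step_type is StepType.TRIGGER_WORKFLOW_ACTION:
                act = s.params.get(cmd("triggers workflow action"))
                if act is not None:
                    try:
                        vocab.workflow_action_of(act)
                    except VocabularyError:
                        diags.append(Diagnostic("error", f"unknown workflow action {act}", ctx))

        # reachability from the trigger: fall-through plus 'then:' jumps;
        # a decision dialogue halts the run
        if triggers and labels:
            reachable: set[str] = set()
            frontier = [triggers[0].label] if triggers else []
            while frontier:
                lab = frontier.pop()
                if lab in reachable or lab not in labels:
                    continue
                reachable.add(lab)
                s = prog.step(lab)
                if s is None:
                    continue
                if s.step_type is StepType.IF_THEN_ELSE:
                    tgt = s.params.get(cmd("then:"))
                    if tgt is not None and str(tgt) in labels:
                        frontier.append(str(tgt))
                if s.step_type is not StepType.DECISION_DIALOGUE:
                    nxt = prog.next_label(lab)
                    if nxt is not None:
                        frontier.append(nxt)
                else:
                    # fall-through from the step *before* a dialogue only
                    # happens via an if-jump; the dialogue itself ends a run
                    pass
            for lab in labels:
                if lab not in reachable:
                    diags.append(Diagnostic("warning", f"step {lab!r} is unreachable", ctx))

        if cls not in template_classes and model.templates:
            diags.append(
                Diagnostic("warning", f"program class {cls} appears in no template", ctx)
            )

    return diags
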