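"""Programmatic source-ontology fixtures: the shared basic ontology and the
specimen min/max entry-form example.

The min/max fixture describes a specimen document whose entry form holds a
row of four components: a label and input field for the minimum number of
individuals of a ranged specimen lot, and a label and input field (sibling
position 4) for the maximum.  The maximum field is required, rendered with
the ``.css-data-input-narrow`` CSS class, validated as a positive integer
and driven by a nine-step program (labels 0, 1A, 2A, 2B, 2C, 3A, 3B, 3C,
3D): trigger with input control, two searches (the specimen individual and
the stored minimum), an if-then-else requiring max > min, an error dialogue
for the failing branch, three triple updates (own stored value, the
assertion on the specimen, the slot on the minimum field) and the 'edit'
workflow action.  The minimum field carries the mirrored program (min must
be smaller than the stored maximum); that program is a reconstruction: only
the maximum field's program is spelled out in the published specimen form.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .engine import Engine
from .lifecycle import TransitionAction
from .source_loader import DEFAULT_NG_BINDINGS
from .vocabulary import (
    InputControlType,
    IfOperation,
    NamedGraphClass,
    Vocabulary,
    WorkflowAction,
)


@dataclass(frozen=True)
class FixtureSpec:
    namespace: str = "https://semcms.dev"
    include_min_field: bool = True
    seed: int = 0


def build_basic_ontology(vocab: Vocabulary) -> Graph:
    """The shared basic ontology: the engine vocabulary plus the default
    workspace binding for the eight named-graph classes."""
    g = vocab.to_graph()
    cmd = vocab.cmd
    for ngc, ws in sorted(DEFAULT_NG_BINDINGS.items(), key=lambda kv: kv[0].value):
        g.add((vocab.ng_class(ngc), cmd("named graph belongs to workspace"), vocab.workspace_term(ws)))
    return g


def _axiom(g: Graph, source, prop, target, params: dict) -> None:
    ax = BNode()
    g.add((ax, RDF.type, OWL.Axiom))
    g.add((ax, OWL.annotatedSource, source))
    g.add((ax, OWL.annotatedProperty, prop))
    g.add((ax, OWL.annotatedTarget, target))
    for p, o in params.items():
        g.add((ax, p, o))


def _step(g: Graph, cls, vocab: Vocabulary, step_cmd_label: str, label: str, params: dict) -> None:
    prop = vocab.cmd(step_cmd_label)
    target = Literal(label)
    g.add((cls, prop, target))
    _axiom(g, cls, prop, target, params)


def build_min_max_fixture(spec: FixtureSpec, vocab: Vocabulary) -> Graph:
    """Source ontology for the specimen document type with the min/max
    positive-integer input fields."""
    g = Graph()
    ns = Namespace(spec.namespace.rstrip("/") + "/sco/specimen/")
    g.bind("sco", ns)
    g.bind("vocab", vocab.ns)
    cmd = vocab.cmd
    var = vocab.var
    empty = var("SPrO_VARIABLE: empty")

    specimen_cls = ns["specimen"]
    g.add((specimen_cls, RDF.type, OWL.Class))
    g.add((specimen_cls, RDFS.label, Literal("ranged specimen lot")))

    max_prop = ns["max-number-of-individuals"]
    g.add((max_prop, RDF.type, OWL.DatatypeProperty))
    g.add((max_prop, RDFS.label, Literal("max number of individuals")))
    min_prop = ns["min-number-of-individuals"]
    g.add((min_prop, RDF.type, OWL.DatatypeProperty))
    g.add((min_prop, RDFS.label, Literal("min number of individuals")))

    gui_narrow = ns["GUI-input-narrow"]
    g.add((gui_narrow, RDFS.label, Literal("GUI_COMPONENT__INPUT_TYPE: .css-data-input-narrow")))
    gui_label = ns["GUI-label"]
    g.add((gui_label, RDFS.label, Literal("GUI_COMPONENT__INPUT_TYPE: .css-label")))
    gui_row = ns["GUI-row"]
    g.add((gui_row, RDFS.label, Literal("GUI_COMPONENT__INPUT_TYPE: .css-row")))

    # ---- entry-component classes
    form_cls = ns["specimen-entry-form-class"]
    row_cls = ns["specimen-row-class"]
    min_label_cls = ns["min-label-class"]
    max_label_cls = ns["max-label-class"]
    min_field_cls = ns["min-input-field-class"]
    max_field_cls = ns["max-input-field-class"]
    for cls in (form_cls, row_cls, min_label_cls, max_label_cls, min_field_cls, max_field_cls):
        g.add((cls, RDF.type, OWL.Class))
    g.add((row_cls, cmd("has GUI representation"), gui_row))
    for cls in (min_label_cls, max_label_cls):
        g.add((cls, cmd("has GUI representation"), gui_label))

    # max field class: GUI representation with tooltip + info text
    g.add((max_field_cls, cmd("has GUI representation"), gui_narrow))
    _axiom(
        g,
        max_field_cls,
        cmd("has GUI representation"),
        gui_narrow,
        {
            cmd("with information text"): Literal("max"),
            cmd("tooltip text"): Literal(
                "REQUIRED INPUT (may not be left empty)! Please provide the maximum "
                "number of individual organisms to which the specimen enumerates."
            ),
        },
    )
    g.add((max_field_cls, cmd("required input [BOOLEAN]"), Literal(True)))

    g.add((min_field_cls, cmd("has GUI representation"), gui_narrow))
    _axiom(
        g,
        min_field_cls,
        cmd("has GUI representation"),
        gui_narrow,
        {
            cmd("with information text"): Literal("min"),
            cmd("tooltip text"): Literal(
                "Please provide the minimum number of individual organisms to "
                "which the specimen enumerates."
            ),
        },
    )

    # ---- instances (the template tree)
    form = ns["specimen-entry-form"]
    row = ns["specimen-row"]
    min_label = ns["min-label"]
    min_field = ns["min-input"]
    max_label = ns["max-label"]
    max_field = ns["max-input"]
    for inst, cls in (
        (form, form_cls),
        (row, row_cls),
        (min_label, min_label_cls),
        (min_field, min_field_cls),
        (max_label, max_label_cls),
        (max_field, max_field_cls),
    ):
        g.add((inst, RDF.type, cls))
    g.add((form, cmd("entry form template of document type"), Literal("specimen")))
    g.add((form, RDFS.label, Literal("specimen entry form")))
    g.add((row, cmd("entry component of"), form))
    g.add((row, cmd("has position in entry component"), Literal("1")))
    for inst, pos, lab in (
        (min_label, "1", "minimum label"),
        (min_field, "2", "minimum number of individuals input field"),
        (max_label, "3", "maximum label"),
        (max_field, "4", "maximum number of individuals input field"),
    ):
        g.add((inst, cmd("entry component of"), row))
        g.add((inst, cmd("has position in entry component"), Literal(pos)))
        g.add((inst, RDFS.label, Literal(lab)))
    # associated-resource slots: the tracked sibling value starts empty, the
    # specimen slot names the domain class and is resolved per document
    g.add((max_field, cmd("has associated instance resource [input_A]"), empty))
    g.add((max_field, cmd("has associated instance resource [input_M]"), specimen_cls))
    if spec.include_min_field:
        g.add((min_field, cmd("has associated instance resource [input_B]"), empty))
        g.add((min_field, cmd("has associated instance resource [input_M]"), specimen_cls))

    # ---- the max field's nine-step program
    comp_ng = vocab.ng_class(NamedGraphClass.DOCUMENT_COMPOSITION)
    asrt_ng = vocab.ng_class(NamedGraphClass.ASSERTIONS)
    from .store import Workspace

    draft_ws = vocab.workspace_term(Workspace.DRAFT)
    ng_cmd = cmd("load from/save to/update in named graph (this document’s specific individual of)")
    ws_cmd = cmd("named graph belongs to workspace")

    _step(g, max_field_cls, vocab, "execution step trigger", "0", {
        cmd("has GUI input type"): vocab.input_control(InputControlType.POSITIVE_INTEGER),
        cmd("input value/resource defines SPrO variable resource"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
        cmd("requirement for triggering the execution step"): var("SPrO_VARIABLE: edit document-access-right for this document"),
    })
    _step(g, max_field_cls, vocab, "execution step: search triple store", "1A", {
        cmd("subject"): var("SPrO_VARIABLE: this entry component"),
        cmd("property"): cmd("has associated instance resource [input_M]"),
        cmd("object"): var("SPrO_VARIABLE:?"),
        ng_cmd: comp_ng,
        ws_cmd: draft_ws,
        cmd("search target"): var("SPrO_VARIABLE: object"),
        cmd("search target defines SPrO variable"): var("SPrO_VARIABLE: associated instance resource [input_M]"),
    })
    _step(g, max_field_cls, vocab, "execution step: search triple store", "2A", {
        cmd("subject"): var("SPrO_VARIABLE: this entry component"),
        cmd("property"): cmd("has associated instance resource [input_A]"),
        cmd("object"): var("SPrO_VARIABLE:?"),
        ng_cmd: comp_ng,
        ws_cmd: draft_ws,
        cmd("search target"): var("SPrO_VARIABLE: object"),
        cmd("search target defines SPrO variable"): var("SPrO_VARIABLE: associated instance resource [input_A]"),
    })
    _step(g, max_field_cls, vocab, "execution step: if-then-else statement", "2B", {
        cmd("has IF input value"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
        cmd("has IF target value"): var("SPrO_VARIABLE: associated instance resource [input_A]"),
        cmd("has IF operation"): vocab.if_operation(IfOperation.SOME_INPUT_LARGER_THAN_TARGET),
        cmd("then:"): Literal("3A"),
    })
    _step(g, max_field_cls, vocab, "execution step: decision dialogue", "2C", {
        cmd("application error message"): Literal("The value must be higher than the value of the minimum number."),
        cmd("end action operation"): vocab.resolve_label("SPrO_OPERATION: ERROR end action"),
    })
    _step(g, max_field_cls, vocab, "execution step: update triple statement(s)", "3A", {
        cmd("subject (this document’s specific individual of)"): max_field_cls,
        cmd("property"): cmd("has user/GUI input [value_B]"),
        cmd("object"): var("SPrO_VARIABLE: to be updated"),
        ng_cmd: comp_ng,
        ws_cmd: draft_ws,
        cmd("update with resource/value"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
    })
    _step(g, max_field_cls, vocab, "execution step: update triple statement(s)", "3B", {
        cmd("subject"): var("SPrO_VARIABLE: associated instance resource [input_M]"),
        cmd("property"): max_prop,
        cmd("object"): var("SPrO_VARIABLE: to be updated"),
        ng_cmd: asrt_ng,
        ws_cmd: draft_ws,
        cmd("update with resource/value"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
    })
    _step(g, max_field_cls, vocab, "execution step: update triple statement(s)", "3C", {
        cmd("subject (this document’s specific individual of)"): min_field_cls,
        cmd("property"): cmd("has associated instance resource [input_B]"),
        cmd("object"): var("SPrO_VARIABLE: to be updated"),
        ng_cmd: comp_ng,
        ws_cmd: draft_ws,
        cmd("update with resource/value"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
    })
    _step(g, max_field_cls, vocab, "execution step: trigger workflow action", "3D", {
        cmd("triggers workflow action"): vocab.workflow_action(WorkflowAction.EDIT),
    })

    if spec.include_min_field:
        # mirrored program for the minimum field (reconstruction): the
        # minimum must be smaller than the stored maximum, read from the
        # slot the maximum field's step 3C writes
        _step(g, min_field_cls, vocab, "execution step trigger", "0", {
            cmd("has GUI input type"): vocab.input_control(InputControlType.POSITIVE_INTEGER),
            cmd("input value/resource defines SPrO variable resource"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
            cmd("requirement for triggering the execution step"): var("SPrO_VARIABLE: edit document-access-right for this document"),
        })
        _step(g, min_field_cls, vocab, "execution step: search triple store", "1A", {
            cmd("subject"): var("SPrO_VARIABLE: this entry component"),
            cmd("property"): cmd("has associated instance resource [input_M]"),
            cmd("object"): var("SPrO_VARIABLE:?"),
            ng_cmd: comp_ng,
            ws_cmd: draft_ws,
            cmd("search target"): var("SPrO_VARIABLE: object"),
            cmd("search target defines SPrO variable"): var("SPrO_VARIABLE: associated instance resource [input_M]"),
        })
        _step(g, min_field_cls, vocab, "execution step: search triple store", "2A", {
            cmd("subject"): var("SPrO_VARIABLE: this entry component"),
            cmd("property"): cmd("has associated instance resource [input_B]"),
            cmd("object"): var("SPrO_VARIABLE:?"),
            ng_cmd: comp_ng,
            ws_cmd: draft_ws,
            cmd("search target"): var("SPrO_VARIABLE: object"),
            cmd("search target defines SPrO variable"): var("SPrO_VARIABLE: associated instance resource [input_A]"),
        })
        _step(g, min_field_cls, vocab, "execution step: if-then-else statement", "2B", {
            cmd("has IF input value"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
            cmd("has IF target value"): var("SPrO_VARIABLE: associated instance resource [input_A]"),
            cmd("has IF operation"): vocab.if_operation(IfOperation.SOME_INPUT_SMALLER_THAN_TARGET),
            cmd("then:"): Literal("3A"),
        })
        _step(g, min_field_cls, vocab, "execution step: decision dialogue", "2C", {
            cmd("application error message"): Literal("The value must be smaller than the value of the maximum number."),
            cmd("end action operation"): vocab.resolve_label("SPrO_OPERATION: ERROR end action"),
        })
        _step(g, min_field_cls, vocab, "execution step: update triple statement(s)", "3A", {
            cmd("subject (this document’s specific individual of)"): min_field_cls,
            cmd("property"): cmd("has user/GUI input [value_B]"),
            cmd("object"): var("SPrO_VARIABLE: to be updated"),
            ng_cmd: comp_ng,
            ws_cmd: draft_ws,
            cmd("update with resource/value"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
        })
        _step(g, min_field_cls, vocab, "execution step: update triple statement(s)", "3B", {
            cmd("subject"): var("SPrO_VARIABLE: associated instance resource [input_M]"),
            cmd("property"): min_prop,
            cmd("object"): var("SPrO_VARIABLE: to be updated"),
            ng_cmd: asrt_ng,
            ws_cmd: draft_ws,
            cmd("update with resource/value"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
        })
        _step(g, min_field_cls, vocab, "execution step: update triple statement(s)", "3C", {
            cmd("subject (this document’s specific individual of)"): max_field_cls,
            cmd("property"): cmd("has associated instance resource [input_A]"),
            cmd("object"): var("SPrO_VARIABLE: to be updated"),
            ng_cmd: comp_ng,
            ws_cmd: draft_ws,
            cmd("update with resource/value"): var("SPrO_VARIABLE: user/GUI input [input_B]"),
        })
        _step(g, min_field_cls, vocab, "execution step: trigger workflow action", "3D", {
            cmd("triggers workflow action"): vocab.workflow_action(WorkflowAction.EDIT),
        })

    return g


def make_engine(spec: FixtureSpec = FixtureSpec()) -> Engine:
    """An engine with the basic ontology and the min/max fixture loaded."""
    engine = Engine(namespace=spec.namespace)
    engine.load_ontology(build_basic_ontology(engine.vocab))
    engine.load_ontology(build_min_max_fixture(spec, engine.vocab))
    return engine


def run_demo(engine: Engine = None, user: URIRef = None) -> list[dict]:
    """Scripted end-to-end walk-through of the specimen min/max form:
    create a document, enter minimum 1 and maximum 5, back it up, publish
    it, and read back the view, history and provenance.  Every step is
    asserted; the transcript is returned as a list of step records."""
    engine = engine or make_engine()
    user = user or URIRef("https://semcms.dev/user/demo")
    session = "session-demo-1"
    engine.open_session(session, user)
    clock = iter(f"2019-08-08T09:00:{i:02d}+00:00" for i in range(60))
    transcript: list[dict] = []

    def log(step: str, **info):
        transcript.append({"step": step, **info})

    record = engine.create_document("specimen", user, next(clock))
    log("create", document=str(record.core_id), graphs=len(
        [r for r in engine.store.graph_registry.values() if str(r.iri).startswith(str(record.core_id))]
    ))

    tree = engine.compose_view(record)
    min_field = next(n for n in tree.walk() if n.info_text == "min")
    max_field = next(n for n in tree.walk() if n.info_text == "max")
    log("view", min_component=str(min_field.component), max_component=str(max_field.component))

    r1 = engine.submit_input(record, min_field.component, "1", user, session, next(clock))
    assert r1.status == "ok", r1
    log("input-min", value="1", status=r1.status)
    r2 = engine.submit_input(record, max_field.component, "5", user, session, next(clock))
    assert r2.status == "ok", r2
    log("input-max", value="5", status=r2.status)

    max_prop = URIRef(engine.namespace + "/sco/specimen/max-number-of-individuals")
    asrt = record.current_draft.assertions_ng.iri
    hits = engine.store.match(None, max_prop, None, asrt)
    assert len(hits) == 1 and str(hits[0][2]) == "5", hits
    log("assertion", predicate=str(max_prop), value=str(hits[0][2]))

    engine.apply_transition(record, TransitionAction.BACKUP, user=user, timestamp=next(clock))
    log("backup", versions=[v.state.value for v in record.versions])
    engine.apply_transition(record, TransitionAction.PUBLISH, user=user, timestamp=next(clock))
    log("publish", versions=[v.state.value for v in record.versions])

    entries, statuses = engine.change_history(record)
    assert len(entries) == 2
    log("history", edits=len(entries), statuses=[s.status for s in statuses])
    chain = engine.provenance_chain(record)
    log("provenance", versions=len(chain), contributors=sorted(str(u) for u in chain[0].contributors))
    return transcript
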