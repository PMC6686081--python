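"""Execute a component's step program in response to a user input event.

A run opens a transaction, executes step '0' (the trigger: access check and
input control) and then the subsequent steps in label order, honoring
'then:' jumps from if-then-else steps.  All triple updates are staged; the
run commits only when the program ends normally.  A validation failure, an
access refusal or a decision dialogue with an ERROR end action rolls the
transaction back, leaving the store exactly as it was - nothing is saved.

Variable bindings live in a per-run environment; the only cross-run
persistence happens through 'has associated instance resource' slot triples
the program itself writes into the composition graph.
"""

from __future__ import annotations

import decimal
import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Union

from rdflib import Literal, URIRef

from .inputcontrol import validate
from .source_loader import ExecutionProgram, ExecutionStepSpec, StepType
from .store import ANY, QuadStore, Term
from .vocabulary import IfOperation, Vocabulary, VocabularyError, WorkflowAction

if TYPE_CHECKING:  # pragma: no cover
    from .lifecycle import DocumentRecord, DocumentVersion

logger = logging.getLogger(__name__)

#: sentinel for an unbound / empty value
EMPTY = object()

_MAX_STEPS = 1000  # guard against cyclic 'then:' jumps


class ConfigurationError(Exception):
    pass


class _Halt(Exception):
    def __init__(self, status: str, message: Optional[str] = None):
        self.status = status
        self.message = message


@dataclass
class ExecutionContext:
    record: "DocumentRecord"
    version: "DocumentVersion"
    component_instance: URIRef
    component_class: URIRef
    user: URIRef
    session: str
    raw_input: str
    timestamp: str
    validated_value: Optional[Term] = None


class VariableEnvironment:
    """Per-run variable bindings plus the built-in resolutions."""

    def __init__(self, vocab: Vocabulary, ctx: ExecutionContext):
        self._vocab = vocab
        self._ctx = ctx
        self.bindings: dict[URIRef, Union[Term, object]] = {}

    def resolve(self, term: Term) -> Union[Term, object, None]:
        """Resolve a parameter term: variables go through the environment,
        anything else stands for itself.  Returns EMPTY for the empty
        variable / unbound-empty bindings and ANY for the '?' placeholder."""
        v = self._vocab
        if term == v.var("SPrO_VARIABLE: empty"):
            return EMPTY
        if term == v.var("SPrO_VARIABLE:?"):
            return ANY
        if term == v.var("SPrO_VARIABLE: this entry component"):
            return self._ctx.component_instance
        if isinstance(term, URIRef) and term in v.variables_by_iri:
            if term not in self.bindings:
                raise _Halt("application_error", f"unbound variable {v.label_of(term)!r}")
            return self.bindings[term]
        return term

    def bind(self, var_iri: URIRef, value: Union[Term, object]) -> None:
        self.bindings[var_iri] = value


@dataclass
class EngineResponse:
    status: str  # ok | validation_error | application_error | access_denied
    messages: list[str] = field(default_factory=list)
    field_feedback: Optional[str] = None  # accept | reject | None
    committed: bool = False


def run_trigger(engine, ctx: ExecutionContext) -> EngineResponse:
    """Run the component class's execution program for one input event."""
    prog: Optional[ExecutionProgram] = engine.model.programs.get(ctx.component_class)
    if prog is None:
        raise ConfigurationError(f"no execution program for component class {ctx.component_class}")
    store: QuadStore = engine.store
    vocab: Vocabulary = engine.vocab
    response = EngineResponse(status="ok")
    env = VariableEnvironment(vocab, ctx)

    store.begin_transaction()
    try:
        current: Optional[str] = "0"
        hops = 0
        while current is not None:
            hops += 1
            if hops > _MAX_STEPS:
                raise ConfigurationError("execution program does not terminate")
            spec = prog.step(current)
            if spec is None:
                raise ConfigurationError(f"program jumps to unknown step {current!r}")
            jump: Optional[str] = None
            if spec.step_type is StepType.TRIGGER:
                exec_trigger_step(engine, ctx, spec, env, response)
            elif spec.step_type is StepType.SEARCH_TRIPLE_STORE:
                exec_search_step(engine, ctx, spec, env, response)
            elif spec.step_type is StepType.IF_THEN_ELSE:
                jump = exec_if_step(engine, ctx, spec, env)
            elif spec.step_type is StepType.DECISION_DIALOGUE:
                exec_dialogue_step(engine, ctx, spec, response)
            elif spec.step_type is StepType.UPDATE_TRIPLES:
                exec_update_step(engine, ctx, spec, env)
            elif spec.step_type is StepType.TRIGGER_WORKFLOW_ACTION:
                exec_workflow_step(engine, ctx, spec)
            current = jump if jump is not None else prog.next_label(current)
    except _Halt as halt:
        store.rollback()
        response.status = halt.status
        if halt.message:
            response.messages.append(halt.message)
        if halt.status == "validation_error":
            response.field_feedback = "reject"
        response.committed = False
        return response
    except Exception:
        store.rollback()
        raise
    store.commit()
    response.committed = True
    return response


def exec_trigger_step(
    engine, ctx: ExecutionContext, spec: ExecutionStepSpec, env: VariableEnvironment, response: EngineResponse
) -> None:
    """Access check plus input control; binds the validated input."""
    vocab: Vocabulary = engine.vocab
    requirement = spec.param(vocab, "requirement for triggering the execution step")
    if requirement == vocab.var("SPrO_VARIABLE: edit document-access-right for this document"):
        if not engine.has_edit_right(ctx.record, ctx.user):
            raise _Halt("access_denied", "user has no edit access right for this document")
    ctl_iri = spec.param(vocab, "has GUI input type")
    try:
        control = vocab.input_control_of(ctl_iri)
    except VocabularyError as exc:
        raise ConfigurationError(str(exc)) from None
    result = validate(control, ctx.raw_input)
    if not result.ok:
        raise _Halt("validation_error", result.message)
    response.field_feedback = "accept"
    ctx.validated_value = result.normalized
    target_var = spec.param(vocab, "input value/resource defines SPrO variable resource")
    if target_var is not None and result.normalized is not None:
        env.bind(target_var, result.normalized)


def _resolve_step_graph(engine, ctx: ExecutionContext, spec: ExecutionStepSpec):
    """The named graph a step loads from / saves to: this document's
    specific individual of the step's named-graph class, checked against
    the step's workspace declaration."""
    vocab: Vocabulary = engine.vocab
    ngc_iri = spec.param(
        vocab, "load from/save to/update in named graph (this document’s specific individual of)"
    )
    if ngc_iri is None:
        raise ConfigurationError(f"step {spec.label!r} names no named graph")
    ngc = vocab.ng_class_of(ngc_iri)
    ref = engine.document_graph(ctx.record, ctx.version, ngc)
    ws_term = spec.param(vocab, "named graph belongs to workspace")
    if ws_term is not None and vocab.workspace_of(ws_term) != ref.workspace:
        return None  # declared workspace does not hold this graph
    return ref


def exec_search_step(
    engine, ctx: ExecutionContext, spec: ExecutionStepSpec, env: VariableEnvironment, response: EngineResponse
) -> None:
    """Match one triple pattern in the step's named graph and bind the term
    at the search-target position; zero matches bind EMPTY."""
    vocab: Vocabulary = engine.vocab
    store: QuadStore = engine.store
    target_var = spec.param(vocab, "search target defines SPrO variable")
    ref = _resolve_step_graph(engine, ctx, spec)
    if ref is None:
        if target_var is not None:
            env.bind(target_var, EMPTY)
        return
    s = env.resolve(spec.param(vocab, "subject"))
    p = env.resolve(spec.param(vocab, "property"))
    o = env.resolve(spec.param(vocab, "object"))
    if EMPTY in (s, p, o):
        hits = []
    else:
        hits = store.match(s, p, o, ref.iri)
    if len(hits) > 1:
        logger.warning(
            "step %s: %d matches for pattern in %s; taking the first in canonical order",
            spec.label, len(hits), ref.iri,
        )
    target = spec.param(vocab, "search target")
    position = {"SPrO_VARIABLE: subject": 0, "SPrO_VARIABLE: object": 2}.get(
        vocab.label_of(target) if target is not None else "SPrO_VARIABLE: object", 2
    )
    if not hits:
        bound: Union[Term, object] = EMPTY
    else:
        bound = hits[0][position]
        if bound == vocab.var("SPrO_VARIABLE: empty"):
            bound = EMPTY
    if target_var is not None:
        env.bind(target_var, bound)


def _as_decimal(value: Term) -> decimal.Decimal:
    try:
        return decimal.Decimal(str(value))
    except decimal.InvalidOperation:
        raise _Halt("application_error", f"non-numeric operand {str(value)!r} for numeric comparison")


def exec_if_step(engine, ctx: ExecutionContext, spec: ExecutionStepSpec, env: VariableEnvironment) -> Optional[str]:
    """Evaluate the IF operation; returns the 'then:' label when true, or
    None to fall through to the next step in order.

    An EMPTY target evaluates true (vacuous): a comparison against a value
    nobody has provided yet must not block the input."""
    vocab: Vocabulary = engine.vocab
    input_val = env.resolve(spec.param(vocab, "has IF input value"))
    target_val = env.resolve(spec.param(vocab, "has IF target value"))
    op = vocab.if_operation_of(spec.param(vocab, "has IF operation"))
    then_label = str(spec.param(vocab, "then:"))
    if target_val is EMPTY:
        return then_label
    if input_val is EMPTY:
        raise _Halt("application_error", "IF input value is empty")
    a, b = _as_decimal(input_val), _as_decimal(target_val)
    if op is IfOperation.SOME_INPUT_LARGER_THAN_TARGET:
        outcome = a > b
    elif op is IfOperation.SOME_INPUT_SMALLER_THAN_TARGET:
        outcome = a < b
    else:  # pragma: no cover
        raise ConfigurationError(f"unhandled IF operation {op}")
    return then_label if outcome else None


def exec_dialogue_step(engine, ctx: ExecutionContext, spec: ExecutionStepSpec, response: EngineResponse) -> None:
    """Report the dialogue's message; an ERROR end action aborts the run
    and nothing is saved to the store."""
    vocab: Vocabulary = engine.vocab
    msg = spec.param(vocab, "application error message")
    message = str(msg) if msg is not None else "The input was rejected."
    end_action = spec.param(vocab, "end action operation")
    if end_action == vocab.resolve_label("SPrO_OPERATION: ERROR end action"):
        raise _Halt("application_error", message)
    response.messages.append(message)


def exec_update_step(engine, ctx: ExecutionContext, spec: ExecutionStepSpec, env: VariableEnvironment) -> None:
    """Stage a replace-object update in the step's named graph."""
    vocab: Vocabulary = engine.vocab
    store: QuadStore = engine.store
    ref = _resolve_step_graph(engine, ctx, spec)
    if ref is None:
        raise _Halt("application_error", f"step {spec.label!r}: named graph not in declared workspace")
    indiv_of = spec.param(vocab, "subject (this document’s specific individual of)")
    if indiv_of is not None:
        subject = engine.document_individual(ctx.record, indiv_of, mint=True)
    else:
        subject = env.resolve(spec.param(vocab, "subject"))
        if subject is EMPTY or subject is ANY or subject is None:
            raise _Halt("application_error", f"step {spec.label!r}: unresolved update subject")
    predicate = spec.param(vocab, "property")
    value = env.resolve(spec.param(vocab, "update with resource/value"))
    if value is EMPTY or value is ANY or value is None:
        raise _Halt("application_error", f"step {spec.label!r}: unresolved update value")
    store.replace_object(ref.iri, subject, predicate, value)


def exec_workflow_step(engine, ctx: ExecutionContext, spec: ExecutionStepSpec) -> None:
    """Dispatch the step's workflow action with the editing context."""
    from . import provenance

    vocab: Vocabulary = engine.vocab
    action_iri = spec.param(vocab, "triggers workflow action")
    try:
        action = vocab.workflow_action_of(action_iri)
    except VocabularyError as exc:
        raise ConfigurationError(str(exc)) from None
    provenance.run_workflow_action(
        engine,
        action,
        {
            "record": ctx.record,
            "version": ctx.version,
            "user": ctx.user,
            "session": ctx.session,
            "timestamp": ctx.timestamp,
            "input_field": ctx.component_instance,
            "new_value": ctx.validated_value if ctx.validated_value is not None else Literal(ctx.raw_input),
        },
    )
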