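"""Compose the DOM-tree-like structured view of a document version.

The view mirrors the nested entry-component hierarchy stored in the
version's composition graph: one node per component, children ordered by
their position (left to right), each node carrying the CSS-class token,
tooltip, information text and required flag from its component class, plus
the value the user has stored in the component so far.  The rendering is a
plain JSON document with stable key order, so it round-trips losslessly.

Composition is read-only on the store.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional

from rdflib import Literal, URIRef
from rdflib.namespace import RDF, XSD

from .store import ANY, QuadStore, Term

if TYPE_CHECKING:  # pragma: no cover
    from .engine import Engine
    from .lifecycle import DocumentRecord, DocumentVersion


class ViewIntegrityError(Exception):
    pass


@dataclass
class ViewNode:
    component: URIRef
    component_class: URIRef
    css_class: Optional[str] = None
    tooltip: Optional[str] = None
    info_text: Optional[str] = None
    required: bool = False
    value: Optional[Term] = None
    position: int = 1
    children: list["ViewNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    @property
    def required_but_empty(self) -> bool:
        return self.required and self.value is None

    def find_by_class(self, class_iri: URIRef) -> Optional["ViewNode"]:
        for node in self.walk():
            if node.component_class == class_iri:
                return node
        return None


def compose_view(engine: "Engine", record: "DocumentRecord", version: "DocumentVersion") -> ViewNode:
    """Build the component tree of one version from its composition graph."""
    store: QuadStore = engine.store
    vocab = engine.vocab
    comp_g = version.composition_ng.iri
    cmd = vocab.cmd
    value_pred = cmd("has user/GUI input [value_B]")

    instances: dict[URIRef, ViewNode] = {}
    parents: dict[URIRef, URIRef] = {}
    for s, _, cls, _ in store.match(ANY, RDF.type, ANY, comp_g):
        if s == comp_g:
            continue
        ann = engine.model.class_annotations.get(cls, {})
        pos = store.value(s, cmd("has position in entry component"), comp_g)
        instances[s] = ViewNode(
            component=s,
            component_class=cls,
            css_class=ann.get("gui_representation"),
            tooltip=ann.get("tooltip"),
            info_text=ann.get("info_text"),
            required=bool(ann.get("required")),
            value=store.value(s, value_pred, comp_g),
            position=int(str(pos)) if pos is not None else 1,
        )
    for s, _, parent, _ in store.match(ANY, cmd("entry component of"), ANY, comp_g):
        if s in instances and parent in instances:
            parents[s] = parent

    roots = [iri for iri in instances if iri not in parents]
    if len(roots) != 1:
        raise ViewIntegrityError(
            f"composition graph must have exactly one root component, found {len(roots)}"
        )
    for child, parent in parents.items():
        instances[parent].children.append(instances[child])
    for node in instances.values():
        node.children.sort(key=lambda n: (n.position, str(n.component)))

    # orphan check: everything must be reachable from the root
    reachable = {n.component for n in instances[roots[0]].walk()}
    orphans = set(instances) - reachable
    if orphans:
        raise ViewIntegrityError(f"orphan components with no path to the root: {sorted(map(str, orphans))}")
    return instances[roots[0]]


def _term_to_json(t: Optional[Term]):
    if t is None:
        return None
    if isinstance(t, Literal):
        out = {"type": "literal", "value": str(t)}
        if t.datatype is not None and t.datatype != XSD.string:
            out["datatype"] = str(t.datatype)
        if t.language:
            out["language"] = t.language
        return out
    return {"type": "iri", "value": str(t)}


def _term_from_json(d) -> Optional[Term]:
    if d is None:
        return None
    if d["type"] == "iri":
        return URIRef(d["value"])
    dt = d.get("datatype")
    return Literal(d["value"], datatype=URIRef(dt) if dt else None, lang=d.get("language"))


def _node_to_dict(node: ViewNode) -> dict:
    return {
        "component": str(node.component),
        "component_class": str(node.component_class),
        "css_class": node.css_class,
        "tooltip": node.tooltip,
        "info_text": node.info_text,
        "required": node.required,
        "required_but_empty": node.required_but_empty,
        "position": node.position,
        "value": _term_to_json(node.value),
        "children": [_node_to_dict(c) for c in node.children],
    }


def _node_from_dict(d: dict) -> ViewNode:
    return ViewNode(
        component=URIRef(d["component"]),
        component_class=URIRef(d["component_class"]),
        css_class=d.get("css_class"),
        tooltip=d.get("tooltip"),
        info_text=d.get("info_text"),
        required=bool(d.get("required")),
        value=_term_from_json(d.get("value")),
        position=int(d.get("position", 1)),
        children=[_node_from_dict(c) for c in d.get("children", [])],
    )


def serialize_view(tree: ViewNode) -> str:
    """Render the tree as a JSON document with stable key order."""
    return json.dumps(_node_to_dict(tree), indent=2, sort_keys=True, ensure_ascii=False) + "\n"


def parse_view(text: str) -> ViewNode:
    return _node_from_dict(json.loads(text))
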