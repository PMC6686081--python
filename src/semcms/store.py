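"""Workspace-partitioned RDF quad store with staged, atomic updates.

The store keeps subject-predicate-object-graph statements (quads) in a
single in-memory set, partitioned logically into six workspaces.  Every
named graph is an explicit, registered object: registering a graph writes
its instantiation statement (graph rdf:type graph-class) and its workspace
assignment into the graph itself, so the partition is self-describing and
survives serialization round-trips.

Terms are plain rdflib terms (URIRef / Literal / BNode); serialization and
parsing of TriG, N-Quads and Turtle are delegated to rdflib.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence, Union

from rdflib import BNode, Dataset, Graph, Literal, URIRef
from rdflib.namespace import RDF

Term = Union[URIRef, Literal, BNode]
#: wildcard for pattern positions
ANY = None


class Workspace(enum.Enum):
    """The six top-level partitions of the store."""

    ONTOLOGY = "ontology"
    ADMIN = "admin"
    CORE = "core"
    DRAFT = "draft"
    PUBLISHED = "published"
    EXTERNAL_ONTOLOGIES = "external_ontologies"


#: predicate used for the self-describing workspace assignment quad
NG_WORKSPACE_PRED = URIRef("https://semcms.dev/vocab/named-graph-belongs-to-workspace")


def workspace_iri(ws: Workspace) -> URIRef:
    slug = "WORKSPACE-BASIC-" + ws.value.replace("_", "-") + "-workspace"
    return URIRef("https://semcms.dev/vocab/" + slug)


_WS_BY_IRI = {workspace_iri(ws): ws for ws in Workspace}


@dataclass(frozen=True)
class NamedGraphRef:
    """A named-graph instance: its IRI, the graph class it instantiates
    and the workspace it belongs to."""

    iri: URIRef
    ng_class: URIRef
    workspace: Workspace


class StoreError(Exception):
    pass


class GraphRegistrationError(StoreError):
    pass


class TransactionError(StoreError):
    pass


class QueryRefusedError(StoreError):
    """Raised when a published-workspace query names a non-published graph."""


Quad = tuple[Term, URIRef, Term, URIRef]


def _term_key(t: Term) -> str:
    # N-Quads lexical form, used for canonical code-point ordering
    return t.n3()


def quad_sort_key(q: Quad) -> tuple[str, str, str, str]:
    s, p, o, g = q
    return (_term_key(g), _term_key(s), _term_key(p), _term_key(o))


class QuadStore:
    """In-memory quad store with registry, pattern matching and staged updates.

    Updates issued while a transaction is open are staged and only applied
    on :meth:`commit`; :meth:`rollback` discards them, leaving the committed
    quad set untouched.  Pattern matching always sees committed quads only.
    """

    def __init__(self) -> None:
        self._quads: set[Quad] = set()
        self._registry: dict[URIRef, NamedGraphRef] = {}
        self._staged: Optional[list[tuple]] = None  # None = no open transaction

    # -- registry ----------------------------------------------------------

    @property
    def workspaces(self) -> tuple[Workspace, ...]:
        """The six workspaces every store is partitioned into."""
        return tuple(Workspace)

    @property
    def graph_registry(self) -> dict[URIRef, NamedGraphRef]:
        return dict(self._registry)

    def register_graph(self, iri: URIRef, ng_class: URIRef, workspace: Workspace) -> NamedGraphRef:
        if iri in self._registry:
            raise GraphRegistrationError(f"named graph already registered: {iri}")
        ref = NamedGraphRef(URIRef(iri), URIRef(ng_class), workspace)
        self._registry[ref.iri] = ref
        # self-describing statements live in the graph itself
        self._quads.add((ref.iri, RDF.type, ref.ng_class, ref.iri))
        self._quads.add((ref.iri, NG_WORKSPACE_PRED, workspace_iri(workspace), ref.iri))
        return ref

    def unregister_graph(self, iri: URIRef) -> None:
        """Drop a graph and every quad stored in it."""
        self._registry.pop(iri, None)
        self._quads = {q for q in self._quads if q[3] != iri}

    def graph_ref(self, iri: URIRef) -> NamedGraphRef:
        try:
            return self._registry[iri]
        except KeyError:
            raise GraphRegistrationError(f"unregistered named graph: {iri}") from None

    def graphs_in_workspace(self, workspace: Workspace) -> list[NamedGraphRef]:
        return sorted(
            (r for r in self._registry.values() if r.workspace == workspace),
            key=lambda r: str(r.iri),
        )

    # -- quads -------------------------------------------------------------

    def __len__(self) -> int:
        return len(self._quads)

    def __iter__(self) -> Iterator[Quad]:
        return iter(sorted(self._quads, key=quad_sort_key))

    def add(self, s: Term, p: URIRef, o: Term, g: URIRef) -> None:
        self._require_registered(g)
        if self._staged is not None:
            self._staged.append(("add", (s, p, o, g)))
        else:
            self._quads.add((s, p, o, g))

    def remove(self, s: Term, p: URIRef, o: Term, g: URIRef) -> None:
        if self._staged is not None:
            self._staged.append(("remove", (s, p, o, g)))
        else:
            self._quads.discard((s, p, o, g))

    def match(
        self,
        s: Optional[Term] = ANY,
        p: Optional[URIRef] = ANY,
        o: Optional[Term] = ANY,
        g: Optional[URIRef] = ANY,
    ) -> list[Quad]:
        """All committed quads matching the pattern, in canonical order
        (graph, subject, predicate, object; N-Quads code-point sort)."""
        out = [
            q
            for q in self._quads
            if (s is ANY or q[0] == s)
            and (p is ANY or q[1] == p)
            and (o is ANY or q[2] == o)
            and (g is ANY or q[3] == g)
        ]
        out.sort(key=quad_sort_key)
        return out

    def value(self, s: Term, p: URIRef, g: URIRef) -> Optional[Term]:
        """Object of the first (canonical-order) matching quad, or None."""
        hits = self.match(s, p, ANY, g)
        return hits[0][2] if hits else None

    def replace_object(self, graph: URIRef, subject: Term, predicate: URIRef, new_object: Term) -> int:
        """Remove every (subject, predicate, *, graph) quad and insert the
        single quad with ``new_object``; staged when a transaction is open.

        Returns the number of quads the replacement removes (counted against
        the committed state at call time)."""
        self._require_registered(graph)
        existing = self.match(subject, predicate, ANY, graph)
        if self._staged is not None:
            self._staged.append(("replace", (subject, predicate, new_object, graph)))
        else:
            for q in existing:
                self._quads.discard(q)
            self._quads.add((subject, predicate, new_object, graph))
        return len(existing)

    def _require_registered(self, g: URIRef) -> None:
        if g not in self._registry:
            raise GraphRegistrationError(f"unregistered named graph: {g}")

    # -- transactions ------------------------------------------------------

    @property
    def in_transaction(self) -> bool:
        return self._staged is not None

    def begin_transaction(self) -> None:
        if self._staged is not None:
            raise TransactionError("transaction already open")
        self._staged = []

    def commit(self) -> None:
        if self._staged is None:
            raise TransactionError("no open transaction")
        staged, self._staged = self._staged, None
        for op, payload in staged:
            if op == "add":
                self._quads.add(payload)
            elif op == "remove":
                self._quads.discard(payload)
            elif op == "replace":
                s, p, o, g = payload
                for q in [q for q in self._quads if q[0] == s and q[1] == p and q[3] == g]:
                    self._quads.discard(q)
                self._quads.add((s, p, o, g))
            else:  # pragma: no cover - internal invariant
                raise TransactionError(f"unknown staged op {op}")

    def rollback(self) -> None:
        if self._staged is None:
            raise TransactionError("no open transaction")
        self._staged = None

    # -- serialization -----------------------------------------------------

    def to_dataset(self) -> Dataset:
        ds = Dataset()
        for s, p, o, g in self._quads:
            ds.graph(g).add((s, p, o))
        return ds

    def serialize(self, format: str = "trig") -> str:
        """Export the committed quad set.  ``trig`` and ``nquads`` preserve
        graphs; ``nquads`` output is canonical (sorted, LF line endings)."""
        fmt = format.lower().replace("-", "")
        if fmt == "nquads":
            return self.canonical_nquads()
        if fmt == "trig":
            return self.to_dataset().serialize(format="trig")
        raise StoreError(f"quad-preserving export requires trig or nquads, not {format!r}")

    def canonical_nquads(self) -> str:
        lines = [
            f"{s.n3()} {p.n3()} {o.n3()} {g.n3()} .\n"
            for s, p, o, g in sorted(self._quads, key=quad_sort_key)
        ]
        return "".join(lines)

    def serialize_graph(self, graph: URIRef, format: str = "turtle") -> str:
        """Single-graph export (Turtle by default)."""
        g = Graph()
        for s, p, o, _ in self.match(g=graph):
            g.add((s, p, o))
        return g.serialize(format=format)

    @classmethod
    def parse(cls, data: Union[str, bytes], format: str = "trig") -> "QuadStore":
        """Rebuild a store from a TriG/N-Quads export.

        The graph registry is reconstructed from the self-describing
        instantiation and workspace-assignment quads written at
        registration time."""
        fmt = format.lower().replace("-", "")
        ds = Dataset()
        try:
            ds.parse(data=data, format={"nquads": "nquads", "trig": "trig"}[fmt])
        except KeyError:
            raise StoreError(f"quad-preserving import requires trig or nquads, not {format!r}") from None
        store = cls()
        quads = [
            (s, p, o, g.identifier if hasattr(g, "identifier") else g)
            for s, p, o, g in ds.quads((None, None, None, None))
        ]
        # registry first: (g, belongs-to-workspace, ws, g) + (g, rdf:type, class, g)
        ws_of: dict[URIRef, Workspace] = {}
        cls_of: dict[URIRef, URIRef] = {}
        for s, p, o, g in quads:
            if s == g and p == NG_WORKSPACE_PRED and o in _WS_BY_IRI:
                ws_of[g] = _WS_BY_IRI[o]
            if s == g and p == RDF.type:
                cls_of[g] = o
        for g, ws in ws_of.items():
            store.register_graph(g, cls_of.get(g, RDF.Statement), ws)
        for s, p, o, g in quads:
            if g in store._registry:
                store._quads.add((s, p, o, g))
            else:
                # tolerate stray default-graph triples by dropping them
                continue
        return store

    def save(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.serialize("trig"))

    @classmethod
    def load(cls, path: str) -> "QuadStore":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.parse(fh.read(), "trig")

    # -- published-workspace queries ---------------------------------------

    def query_published(
        self,
        patterns: Sequence[tuple],
        graphs: Optional[Iterable[URIRef]] = None,
    ) -> list[dict[str, Term]]:
        """Evaluate a basic-graph-pattern query restricted to graphs in the
        published workspace.

        ``patterns`` is a sequence of (s, p, o) triples whose positions are
        rdflib terms or variable names (strings starting with '?').  Rows
        are returned as variable-binding dicts in deterministic order, via
        nested-loop join.  Naming a graph outside the published workspace
        raises :class:`QueryRefusedError`.
        """
        published = {r.iri for r in self._registry.values() if r.workspace == Workspace.PUBLISHED}
        if graphs is not None:
            graphs = list(graphs)
            for g in graphs:
                if g not in published:
                    raise QueryRefusedError(f"graph {g} is not in the published workspace")
            scope = set(graphs)
        else:
            scope = published
        pool = [q for q in sorted(self._quads, key=quad_sort_key) if q[3] in scope]

        def is_var(x) -> bool:
            return isinstance(x, str) and not isinstance(x, (URIRef, Literal, BNode)) and x.startswith("?")

        rows: list[dict[str, Term]] = [{}]
        for s, p, o in patterns:
            next_rows: list[dict[str, Term]] = []
            for binding in rows:
                for qs, qp, qo, _ in pool:
                    new = dict(binding)
                    ok = True
                    for pat, val in ((s, qs), (p, qp), (o, qo)):
                        if is_var(pat):
                            if pat in new and new[pat] != val:
                                ok = False
                                break
                            new[pat] = val
                        elif pat is not ANY and pat != val:
                            ok = False
                            break
                    if ok:
                        next_rows.append(new)
            rows = next_rows
        # deduplicate while keeping deterministic order
        seen, out = set(), []
        for r in rows:
            key = tuple(sorted((k, _term_key(v)) for k, v in r.items()))
            if key not in seen:
                seen.add(key)
                out.append(r)
        return out


def create_store(persistence_path: Optional[str] = None) -> QuadStore:
    """Create a fresh store (loading from ``persistence_path`` if it exists).

    Every store carries the six workspaces; graphs are registered into them
    as documents are created."""
    if persistence_path:
        import os

        if os.path.exists(persistence_path):
            return QuadStore.load(persistence_path)
    return QuadStore()
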