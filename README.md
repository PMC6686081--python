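# semcms

Ontology-controlled document management over an RDF quad store.

`semcms` is a content-management engine for FAIR scientific data in which
the application itself is described declaratively inside RDF/OWL
*source-code ontologies*: entry forms, input validation, data schemes, the
document life cycle and all provenance tracking are annotations on
ontology classes and individuals, written with a small command vocabulary
(annotation properties acting as commands, individuals acting as runtime
variables such as `SPrO_VARIABLE: empty`). The engine interprets those
descriptions at run time — changing a form or a storage rule means editing
an ontology, not code. It is aimed at research-data repositories (the
motivating use case is specimen collections in biodiversity informatics)
that need structured entry forms in front of queryable knowledge graphs.

## What the engine does

* **Workspace-partitioned quad store** — all data and metadata live as
  subject–predicate–object–graph statements in one store partitioned into
  six workspaces (`ontology`, `admin`, `core`, `draft`, `published`,
  `external_ontologies`). Named graphs are first-class, registered objects
  modeled as ontology instances; TriG / N-Quads / Turtle round-trips are
  exact, and a restricted basic-graph-pattern query interface exposes only
  the published workspace.
* **Declarative entry forms** — a form is a nested hierarchy of entry
  components (`entry component of`, `has position in entry component`);
  each component class carries its CSS representation, tooltip, required
  flag and a labeled program of execution steps (`0`, `1A`, `2A`, …):
  trigger (access check + input control), search, if–then–else, decision
  dialogue, triple update and workflow action. A run is transactional: if
  it fails, nothing is saved to the store.
* **Document life cycle** — versioned documents move through
  current/saved/recycle/deleted draft and current/previously published
  states via `create`, `backup`, `to bin`, `restore`, `delete`, `publish`
  and `revise`, with guards (at most one current draft, publishing erases
  every draft, revising requires no draft) enforced by the engine.
* **Provenance and change history** — every version gets a provenance
  entry (creator, creation time, predecessor, contributors) and every
  editing step is logged as a chain of entry states in time (timestamp,
  user, session, input field, new value) twinned with a chain of document
  statuses linked by transition processes.
* **Input control** — seventeen validators (Boolean, click, phone number,
  email address, composite literal, GeoJSON string, literal, date, date
  time, decimal degree, float, float pH, float percentage, decimal
  latitude, decimal longitude, integer percentage, positive integer), each
  with a stable error message, producing typed RDF literals.

## Worked example

The bundled fixture reproduces a specimen entry form with a minimum and a
maximum "number of individuals" field; the maximum field (sibling
position 4 in its row, required, validated as a positive integer) runs a
nine-step program that stores the value only if it exceeds the minimum.

```python
from rdflib import URIRef
from semcms import make_engine, TransitionAction

engine = make_engine()
user = URIRef("https://semcms.dev/user/demo")
record = engine.create_document("specimen", user, "2019-08-08T09:00:00+00:00")

tree = engine.compose_view(record)
min_field = next(n for n in tree.walk() if n.info_text == "min")
max_field = next(n for n in tree.walk() if n.info_text == "max")

engine.submit_input(record, min_field.component, "1", user, "s1", "2019-08-08T09:00:01+00:00")
resp = engine.submit_input(record, max_field.component, "5", user, "s1", "2019-08-08T09:00:02+00:00")
print(resp.status)                      # ok
resp = engine.submit_input(record, max_field.component, "1", user, "s1", "2019-08-08T09:00:03+00:00")
print(resp.status, resp.messages[0])    # application_error The value must be higher than the value of the minimum number.

engine.apply_transition(record, TransitionAction.PUBLISH, user=user,
                        timestamp="2019-08-08T09:00:04+00:00")
rows = engine.query_published([
    ("?specimen", URIRef("https://semcms.dev/sco/specimen/max-number-of-individuals"), "?max"),
])
print(str(rows[0]["?max"]))             # 5
```

The same walk-through is scripted as `semcms demo` (or
`python -c "from semcms import run_demo; run_demo()"`), which creates a
document, enters minimum 1 and maximum 5, backs up, publishes, and prints
the resulting view, change history and provenance chain as a transcript.

A CLI covers the full surface: `semcms init`, `semcms doc
create|input|backup|to-bin|restore|delete|publish|revise|status|view|history`,
`semcms query --pattern …`, `semcms export --format trig|nquads`.

## Layout

| module | contents |
| --- | --- |
| `semcms.store` | quad store, workspaces, transactions, serialization, published-workspace queries |
| `semcms.vocabulary` | command/variable/value registry, enumerations, Turtle export |
| `semcms.inputcontrol` | the seventeen input validators |
| `semcms.source_loader` | source-ontology parsing: templates, step programs, diagnostics |
| `semcms.lifecycle` | URI minting, graph networks, the version state machine |
| `semcms.provenance` | provenance entries, change-history chains, workflow actions |
| `semcms.interpreter` | transactional execution of step programs |
| `semcms.view` | DOM-like structured view composition and JSON round-trip |
| `semcms.fixtures` | basic ontology + specimen min/max fixture + scripted demo |
| `semcms.cli` | the `semcms` command-line tool |

See `docs/methods.md` for the data model, the design decisions and the
known limitations.
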