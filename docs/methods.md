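# Methods

This note describes the data model the engine maintains, the execution
semantics of the step interpreter, the choices made where the design was
genuinely open, and what the bundled fixtures do and do not exercise.

## Store model

The store is a single in-memory set of quads (subject, predicate, object,
named graph) over rdflib terms, partitioned logically into six workspaces:
`ontology`, `admin`, `core`, `draft`, `published` and
`external_ontologies`. Physical separation into one RDF store per
workspace is an implementation freedom we do not take: a logical partition
keyed on the graph registry gives the same visibility semantics (draft
data invisible to published-workspace queries) with far simpler
transactional bookkeeping.

Every named graph is registered before use, as an instance of a
named-graph class assigned to exactly one workspace. Registration writes
two self-describing quads into the graph itself — its `rdf:type` link to
the graph class and its workspace assignment — so a TriG or N-Quads dump
carries enough information to rebuild the registry on parse; round-trips
are exact on the quad set.

Determinism conventions:

* `match` returns quads sorted by (graph, subject, predicate, object) on
  their N-Quads lexical forms, code-point order. Any "take the first
  match" rule in the interpreter therefore has a reproducible outcome.
* The canonical export is sorted N-Quads, UTF-8, LF line endings; tests
  compare failed-run behavior byte-for-byte against it.
* Blank nodes are never written into document graphs; all minted nodes
  (components, individuals, chain nodes) get IRIs under the document's
  namespace, so graphs can be copied and cited stably.

Updates issued inside a transaction are staged as an ordered operation
list and applied only on commit; rollback discards them. `replace_object`
(remove all objects of a subject–predicate pair in one graph, insert the
new one) is the primitive the interpreter's update steps use; replaying
it is idempotent.

Typed literals: form input is stored with the datatype implied by its
input control (positive integer → `xsd:integer`, float ranges →
`xsd:decimal`, date/date-time → `xsd:date`/`xsd:dateTime`); bare strings
default to `xsd:string` semantics.

The published-workspace query interface evaluates basic graph patterns
(conjunctive triple patterns with shared variables) by nested-loop join
over published-workspace quads only, returning rows in deterministic
order. Full SPARQL is deliberately out of scope: every engine-internal
search is a single pattern, and the store can be exported to any external
SPARQL endpoint via TriG.

## Command vocabulary

Commands (annotation properties such as `entry component of`, `has GUI
input type`, `then:`), variables (`SPrO_VARIABLE: empty`,
`SPrO_VARIABLE:?`, `SPrO_VARIABLE: this entry component`, …), IF
operations, workflow actions, the eight named-graph classes and the
seventeen input-control types are registered in a bijective label ↔ IRI
table. IRIs are minted under a configurable base namespace
(`https://semcms.dev/vocab/` by default) by slugifying the label, so the
package is self-contained; an alias table can map them onto externally
published vocabularies. Labels are matched exactly, including bracketed
suffixes; because source material mixes `[input M]` and `[input_M]`, the
space form is accepted as an alias of the underscore form.

## Source-code ontologies

A source ontology describes one or more document types. Instance-level
annotations give the form tree: `entry component of` links child to
parent, `has position in entry component` orders siblings left-to-right,
and `has associated instance resource [·]` slots hold per-component
tracked values (initially the `empty` variable). Class-level annotations
give everything shared by all instances of a component class: the GUI
representation (a CSS-class token), tooltip and information text (as OWL
axiom annotations on the GUI-representation annotation), the required
flag, and the execution-step program. The two levels are disjoint
concerns; nothing at the instance level overrides the class level.

Two step encodings are accepted: the OWL axiom-annotation form (the step
command annotates the class with the step label; subcommands live on the
reifying `owl:Axiom` node) and a flattened form in which the step command
points at a dedicated step node carrying `rdfs:label` and the parameters
as direct properties. Loading is insensitive to RDF statement order.

Step labels are a number plus an optional capital letter; the total order
is numeric-major, letter-minor (`0` < `1A` < `2A` < `2B` < `2C` < `3A`).
Each step type has mandatory parameters (trigger: the input control;
search: subject/property/object/search target; if: input, target,
operation, `then:`; dialogue: end action; update: property, object,
update source; workflow: the action). A missing mandatory parameter is a
load error naming the component class and step label (or a collected
diagnostic in lenient mode). `validate_source` additionally reports
dangling `then:` targets, unknown IF operations / input controls /
workflow actions, unreachable steps, duplicate sibling positions
(warning; ties break by IRI sort) and required component classes without
a trigger program.

## Document life cycle

Document and version IRIs follow
`namespace/resource/UniqueNumber-YearMonthDay-DocumentType-VersionNumber`;
the document-level (core) IRI is the same pattern without the version
suffix. The unique number is a per-store monotonic counter persisted in
the admin workspace; version numbers increase monotonically across all
versions of a record, drafts and published alike, so the IRI pattern
stays injective per record.

Creating a document registers seven graphs: five version-independent ones
in the core workspace (core document contents, versions and provenance,
change log, document-specific access rights, core document individuals)
and two version-dependent ones in the draft workspace (document
composition — a deep copy of the form template with fresh component IRIs —
and assertions). The core-document-contents graph lists all seven,
itself included. Slot values that name a domain class (e.g. the specimen
class) are resolved at copy time to *this document's specific individual*
of that class, minted into the core-document-individuals graph; all
copied components are listed there too with their `rdf:type`.

Transitions and guards:

* `backup` copies the current draft's composition/assertions graphs into
  a new saved-draft version (the current draft remains). Core graphs are
  shared across versions, matching the version-independent/version-
  dependent split.
* `to bin` turns the current draft — or, by explicit version number, a
  saved draft — into a recycle draft. The action is offered at record
  level only while a current draft exists.
* `restore` promotes the newest saved or recycle draft (or an explicit
  one) to current draft; only possible when no current draft exists.
* `delete` erases a recycle draft's version-dependent quads and graphs,
  keeping the version entry and the delete-process status node as
  metadata. When nothing but deleted drafts would remain, the entire
  record and all its graphs are removed.
* `publish` requires every required component to have a value (the view
  layer flags required-but-empty fields; publishing is refused with the
  offending component list). It mints a new current published version in
  the published workspace, demotes a prior current published version to
  previously published, erases every draft version (current, saved,
  recycle — and drops deleted-draft entries as well), and rewrites a
  pointer from every previously published version to the new current one.
  Digital-object-identifier registration is out of scope; the version
  entry is the citable anchor.
* `revise` copies the current published version into a new current draft;
  only possible when no version is in any draft state (current, saved or
  recycle).

At all times a record holds at most one current draft and at most one
current published version. Every applied transition appends exactly one
status node to the change-history graph. The test suite model-checks
these rules against an independently coded reference automaton that
tracks only the ordered list of version states, over every reachable
(state, action) pair to depth 6 and 500 random action sequences to depth
8.

## Provenance and change history

The versions-and-provenance graph holds one entry per version: creator,
creation time (`xsd:dateTime`), version number, predecessor version,
contributor set and an interval (start at creation; the predecessor's end
is stamped when a successor appears). The change-history graph holds two
linear chains: entry states in time — each editing step fills the newest
state's logged change (timestamp, user, session, input field, new value;
all five mandatory) and appends a fresh state with a yet empty logged
change, so after *n* edits the chain has *n*+1 nodes — and document
statuses in time, each linked to its predecessor through the transition
process that produced it.

Predicates in these graphs are surrogate IRIs minted in the engine
namespace with labels mirroring the provenance/versioning/time-interval
semantics they express (`previous version`, `created by`, `contributed
by`, `interval start`, …); an alias table can export them onto published
metadata vocabularies. The exact external triple patterns are an
interpretation, since only their intent, not their serialization, was
available.

The `edit` workflow action bundles the tracking: add the user to the
version's contributor set, record the document in the user's own
contribution list (a per-user graph in the admin workspace) and append
the change-log entry. Sessions are opaque caller-supplied identifiers
held in an in-memory registry. Since entries capture the full input
event, replaying a history through the interpreter over a freshly created
twin document reproduces the composition and assertions graphs exactly;
this replay equivalence is asserted in the tests.

## Interpreter semantics

A run executes one component class's program for one raw input event.
The whole run is wrapped in a store transaction: updates, log entries and
contributor bookkeeping are staged, and only a normal program end
commits. Validation failure, a missing edit right and the ERROR end
action all roll back — the store's canonical dump is byte-identical
afterwards. The no-save rule is stated for the error path of the worked
example; we generalize it to full transactional semantics for
crash-safety.

Step dispatch:

* **trigger (`0`)** — checks the edit access right once per run (the
  requirement is attached to the trigger step only), validates the raw
  input against the declared control, binds the typed literal to the
  declared variable and sets the accept/reject field feedback.
* **search** — resolves the pattern (variables from the environment, `?`
  as wildcard, `this entry component` from the context), resolves the
  named graph as this document's individual of the declared graph class,
  checks the declared workspace, and binds the term at the search-target
  position. Zero matches — or a slot still holding the `empty` marker —
  bind EMPTY; several matches take the first in canonical order and log a
  warning; a workspace mismatch binds EMPTY rather than erroring.
* **if–then–else** — numeric comparison on decimal-parsed operands;
  strict inequality (equality falls to the error branch). An EMPTY target
  evaluates true: a maximum entered before any minimum must not be
  rejected against a value nobody provided. A non-numeric operand halts
  with an application error. Two operations are registered: input larger
  than target, and its mirror, input smaller than target (needed by the
  reconstructed minimum-field program). One jump target per IF step;
  chained conditions are separate steps executed in label order,
  falling through on false.
* **decision dialogue** — reports its message; the ERROR end action
  halts and rolls back.
* **update** — resolves the target graph as above; the subject is given
  directly, through a variable, or as "this document's specific individual
  of" a class (looked up in the core-document-individuals graph and
  minted if absent); the object slot must be the `to be updated`
  variable; the value comes from the declared source variable. Executes
  as a staged `replace_object`. Unresolved variables halt with an
  application error and roll back.
* **workflow** — dispatches the declared action with the editing context
  (field, validated value, user, session, timestamp).

Variable scope is one run; nothing persists in the environment between
runs. Cross-run persistence happens only through the associated-resource
slot triples the programs themselves write (the maximum field's step 3C
stores its value in the minimum field's slot, and vice versa).

## View composition

`compose_view` reads one version's composition graph into a tree: one
node per component, children ordered by position (ties by IRI), class
metadata (CSS token, tooltip, info text, required flag) joined in from
the loaded model, the stored user input as the node value, and a
required-but-empty flag that the publish guard consumes. Orphan
components and multiple roots are integrity errors. Composition is
read-only on the store; the JSON rendering has stable key order and
round-trips to an equal tree.

## Fixtures and what they show

`build_basic_ontology` emits the vocabulary plus the default workspace
binding of the eight graph classes (core-document graphs in the core
workspace; composition and assertions in the draft workspace).
`build_min_max_fixture` emits the specimen document type: one row with
min label, min input, max label and max input (positions 1–4); the
maximum field required, narrow-input CSS class, tooltip and info text,
and the nine-step program (0, 1A, 2A, 2B, 2C, 3A, 3B, 3C, 3D) that
validates a positive integer, finds the specimen individual and the
stored minimum, requires max > min, stores the value in the composition
graph, the assertions graph and the minimum field's slot, and triggers
the `edit` action. The minimum field carries the mirrored program with
the comparison reversed; that program is a reconstruction (only the
maximum field's program is published), labeled as such in the module
docstring.

The fixture exercises the engine's full vertical slice — declarative
loading, transactional interpretation, lifecycle, provenance, views — but
it is deliberately small: one document type, one data property pair, one
input-control type on the hot path, single-user sessions. Passing tests
therefore demonstrate the engine's mechanics, not scale behavior
(thousands of components, concurrent editors) or the breadth of real
instance ontologies. Test problem sizes were chosen accordingly: stores
up to 10³ quads with 50 random patterns for the matching oracle,
model-check depth 6 exhaustive / 500 random sequences of depth ≤ 8, and
five-edit histories for the chain properties.

## Known limitations

* Single-writer contract per document; callers serialize concurrent
  edits.
* No OWL reasoning over source ontologies; annotations are read
  syntactically.
* No text-index-backed autocomplete for external ontology terms (the
  external-ontologies workspace exists but is not populated by the
  fixtures).
* Access rights are a flat per-document edit right; finer-grained
  categories (read-only, publish) are not modeled.
* Data-creator vs document-creator distinction is not implemented;
  contributors are tracked as one set.
* Whether deleted-draft entries should survive a publish is ambiguous in
  the life-cycle description; we remove them on publish and note the
  alternative here.
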