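# Methods

## Data model

A project is a closed set of five element kinds, each carrying a typed
identifier (one-letter kind tag + serial: `P` project, `C` collection, `I`
item, `R` rule, `S` statement).  Serials are allocated monotonically per
project so that generated fixtures and serializations are reproducible;
the identifiers are otherwise opaque.

* A **collection** groups items and belongs to the project.
* A **rule** (TBox) is a schema edge: subject collection, verb, and either
  an object collection ("link rule") or a literal type tag drawn from
  `text | date | number`.
* A **statement** (ABox) instantiates exactly one rule for one item, with
  an item value for link rules and a literal otherwise.

Two invariants are re-checked after every load, import and mutation:
referential closure (every referenced id resolves, value kinds match their
rule) and the TBox/ABox partition (no element is both a rule and a
statement).  Cycles among link rules are legal data; every traversal in the
package (layout, child resolution) is single-hop or carries a visited set,
so it terminates regardless.

RDF serialization uses a package-local namespace
(`https://gboxui.invalid/vocab#`) with terms
`Project/Collection/Item/Rule/Statement`, `subject/verb/object`,
`instanceOf`, `value`, `label`, `identifier`, `inProject/inCollection` and
`accessKey`; the model itself prescribes no IRIs, so any stable vocabulary
is equivalent up to renaming.  `save∘load` and `load∘save` are identities
up to blank-node naming, checked by graph isomorphism.  Authentication is
modeled as an opaque per-project key compared for equality — sufficient to
exercise the "different keys, different views" behaviour without any user
machinery.

`expand_triples` flattens the store into exactly one dyadic triple per rule
(subject collection, rule IRI as predicate, object) and one per statement
(item, rule IRI, value).  Using the rule IRI as the predicate of both its
schema triple and its instantiations keeps emitted queries one pattern per
condition; queries restrict subjects to item IRIs so schema triples never
masquerade as data.

### Tabular import

The importer maps columns to literal rules, with one designated key column
identifying (or creating) the subject item in a root collection.  Exactly
one literal statement is created per non-empty mapped cell; empty cells
produce nothing (absence, not empty string, which downstream displays as an
inactive field).  When a mapped rule lives on a child collection, a
per-row child item is created once and attached through the root→child
link rule — one extra link statement per new child item; without this the
imported values would be unreachable by two-level searches.  Idempotence is
obtained by keying statements on `(item, rule, value)`: re-importing an
identical row creates nothing.

## Graphic model

The GBox is deliberately closed: a registry of exactly 11 action types
(a twelfth registration raises) crossed with 5 descriptor slots.  Six
action names are fixed by the model; the remaining five are
package-defined — `hasTab`, `hasLabel`, `hasHidden`, `hasLink`,
`hasTestValue` — chosen to cover tab creation, labelling, hiding,
cross-references and the trigger-test behaviour the slot semantics imply.
Each action's `slot_profile` is exact: a valid instance fills the mandatory
`domain` plus precisely the profile slots, which makes validation a set
equality checked exhaustively (11 actions × 16 presence combinations) in
the tests.

Instances also project to plain triples — subject = domain (composed with
the trigger for test actions), predicate = action name, object = range
(composed with the value) — using a percent-escaped `|` composite that is
exactly invertible.  The triple view returns a deterministically ordered
list rather than a set so the inverse restores document order, which drives
display order.

Open design points resolved here: trigger matching is exact, case-sensitive
string equality; formula fields use arithmetic (`+ - * /`, parentheses)
over `{field label}` references to sibling components, evaluated by a
restricted AST walker (no names, no calls), returning blank on any missing
or non-numeric operand; conflicting instances on the same component follow
last-writer-wins with a logged warning.

## Assembly

`default_layout` derives the GBox-absent interface from topology alone: the
target collection is the aggregation root, each collection reachable in one
hop through a link rule becomes a tab, and each literal rule becomes a row
component with provenance `"default"`.  One hop is the default because
deeper nesting is an explicit graphic choice (`hasSubCollections`), not a
property of the schema; the same algorithm applies unchanged when the
interface is retargeted at any other collection.

`assemble` overlays instances in document order.  Component actions rewrite
the component bound to their domain rule (kind, options, formula, active
flag); structural actions annotate or augment the tab tree — augmentation
never removes a tab created by the domain structure, a property tested
across instance prefixes.  Test actions are deferred into the document's
trigger list and evaluated per item by `apply_triggers`, which also fills
field values (following one link hop for child-collection rules, marking
absent values inactive) and recomputes formulas last so triggered values
participate.

Outputs are deterministic: canonical JSON uses sorted keys, UTF-8, LF and a
trailing newline, enabling byte-level golden-file and reproducibility
tests; HTML rendering is static HTML5 in which every component is exactly
one element carrying `data-kind` and `data-provenance` attributes (labels
ride as `aria-label`), so the component multiset survives a parse-back.
Rendering is server-side and script-free, keeping the interface model
assertable headlessly.

## Query engine

Selections are conjunctive (AND) only, with `equals` (exact) and `contains`
(case-insensitive substring) comparators; date literals are ISO-8601, which
makes lexicographic comparison consistent with chronology.  The planner
finds the parent as the collection that links to every other referenced
collection and rejects deeper-than-two-level selections with an error
naming the missing link.  Execution joins parent items to filtered child
items through link statements; filter-less children contribute projection
values only and never constrain the parent set (mirrored by `OPTIONAL` in
the emitted SPARQL).  Result rows are sorted by parent item identifier.

The emitted SPARQL consists of an enumerator pattern (parent bound through
the parent collection's rules, restricted to item IRIs), one pattern per
parent filter, and per child one link pattern plus one pattern per child
filter — hence an affine triple-pattern count in the number of child
nodes, the structural counterpart of linear query-cost scaling.  The
engine's results are cross-checked two independent ways: a brute-force
statement-scan oracle (no indexes, no joins) and execution of the emitted
SPARQL by rdflib over the flattened triples.

## Invocation protocol

Exactly 7 parameters, 3 mandatory (`URLDATA`, `KEYDATA`, `URLGUI`).  The
protocol fixes only the mandatory trio and the composite
`location|resource-id` dialect; the four optional parameters are chosen
here as `KEYGUI`, `RESOURCE`, `GUIPROJECT` and `FORMAT` — the graphic key,
the two ids otherwise embedded in the composites, and the one remaining
output degree of freedom.  Locators accept local file paths as well as
URLs so the pipeline runs desk-scale without a network service.  `run`
executes the four pipeline stages (load sources, split domain/graphic,
translate to the document model, merge and render), logging each with its
elapsed time, and is byte-reproducible for identical inputs.

## Synthetic data

The generator emulates a gastric-oncology trial schema: a "Patient ID"
root with a participant-number rule, aggregating Demographics (name,
gender, date of birth, smoking status), Histology (tumor grade incl. "G2
moderately differentiated", tumor type), Tissue (sample type, collection
date, storage location) and Treatment (regimen, cycles, dose).  Value
vocabularies ship as editable YAML so tests can pin exact expected query
results.  Each patient gets one item per collection, one link statement
per child, and one literal statement per literal rule drawn from a
`random.Random(seed)` stream — hence the closed forms: literal statements
= n_patients × literal rules, link statements = n_patients × link rules,
and byte-identical serializations under a fixed seed.  An optional
per-rule missingness rate (default 0) exercises inactive-field and
failed-trigger paths.

What the fixtures do *not* emulate: realistic clinical value distributions,
longitudinal or repeated measurements, multi-valued fields, missingness
correlated across fields, or production-scale stores.  Passing tests
therefore demonstrate structural and semantic correctness of the assembly
and query machinery, not statistical fidelity to real trial data, and no
wall-clock performance claims are made — problem sizes in the tests and
acceptance script (50 seeded 2-patient projects for assembly equivalence,
one 50-patient project and 200 random plans for the query oracle, 50 plans
for SPARQL cross-execution) were chosen as the smallest sizes that still
exercise every code path with non-trivial result sets.

## Known limitations

* Single-project stores; no federation across deployments, no network
  service, no SQL backbone.
* Two-level queries only, conjunctive only; OR and negation are out of
  scope.
* The default layout traverses one hop; deeper nesting requires explicit
  `hasSubCollections` annotations.
* The five package-defined action names fill the registry to its fixed
  cardinality but are not a published vocabulary; documents using them are
  portable only among consumers of this package.
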