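# gboxui

Autonomous assembly of tabbed data-entry interfaces from RDF knowledge
bases, with a conjunctive query engine that turns form selections into
SPARQL.

Clinical-trials data capture is schema-volatile: new assays, new
collaborators and new research questions keep reshaping the data model, and
a hand-coded web form goes stale with every change.  `gboxui` addresses this
by treating the interface itself as derivable knowledge.  A knowledge base
is kept in three explicitly separated parts:

* **TBox** — terminology: *rules*, schema edges linking a subject
  *collection* (a class-like node such as "Patient ID" or "Demographics")
  to another collection or to a literal type (`text | date | number`);
* **ABox** — assertions: *statements*, which instantiate a rule for a
  concrete *item* with a value;
* **GBox** — graphic descriptors: a fixed registry of **11 GUI actions**
  (`hasSubCollections`, `hasText`, `hasDate`, `hasFormula`,
  `hasFieldInactive`, `hasOptions`, plus five package-defined complements)
  crossed with **5 GUI-rule slots** (`domain`, `range`, `action`,
  `trigger`, `value`).

From the TBox/ABox alone the assembler derives a default interface —
collections become tabs, literal rules become rows — so a missing GBox
never blocks assembly.  GBox instances then refine it: a rule annotated
`hasDate` renders as a date input, `hasOptions` as a drop-down,
`hasFormula` as a field recomputed from its siblings, and a test action
writes its configured value into the range component whenever an item's
statement under the domain rule equals the trigger.  Because the graphic
annotation is decoupled from the data, different descriptor projects (and
different access keys) yield entirely different views of the same records.

Search is conjunctive and at most two levels deep: filters on a single
collection run directly; filters spanning linked collections are planned as
a parent node plus child nodes joined through link statements, and emit
SPARQL 1.1 SELECT text whose triple-pattern count grows by a constant per
added child node.

## Worked example

```python
from gboxui import (FixtureConfig, generate_project, generate_gbox,
                    assemble, Filter, build_plan, execute)

kb = generate_project(FixtureConfig(n_patients=30, seed=5))   # synthetic trial
gbox = generate_gbox(kb)
ui = assemble(kb, gbox, kb.root_collection().id)
print("tabs:", [t.label for t in ui.tabs[0].sub_tabs])
print("components:", len(ui.all_components()))

def f(verb, literal, comparator="equals"):
    rule = kb.rule_by_verb(verb)
    return Filter(node=rule.subject, rule=rule.id,
                  comparator=comparator, literal=literal)

plan = build_plan(
    [f("participant number", "10", "contains"),
     f("gender", "female"),
     f("tumor grade", "G2 moderately differentiated")],
    [kb.rule_by_verb("name").id], kb)
print("plan nodes:", plan.node_count)
print(execute(plan, kb).to_csv())
```

prints

```
tabs: ['Demographics', 'Histology', 'Tissue', 'Treatment']
components: 14
plan nodes: 3
item,name
1001,Lena Marsh
1006,Iris Wong
1012,Jonas Reis
1015,Alex Souza
1017,Lena Marsh
1025,Lena Marsh
```

The synthetic project roots a "Patient ID" collection that aggregates four
child collections, so the assembled interface carries one tab per child.
The three filters span three collections (participant number on the root,
gender on Demographics, tumor grade on Histology), giving a
parent-plus-two-children plan — 3 nodes — whose result set is the patients
that are female *and* have a G2 moderately differentiated tumor.

The same pipeline is scriptable from the shell:

```sh
gboxui demo --out-dir demo --seed 5 --patients 30   # project + GBox + ui.html
gboxui assemble --url "URLDATA=demo/project.ttl|C2&KEYDATA=demo-key&URLGUI=demo/gui-rules.ttl&KEYGUI=demo-gui-key" --out ui.html
gboxui search --urldata demo/project.ttl --keydata demo-key --filter "R13=female" --project-rule R7
```

The invocation protocol recognizes exactly 7 parameters (`URLDATA`,
`KEYDATA`, `URLGUI`, `KEYGUI`, `RESOURCE`, `GUIPROJECT`, `FORMAT`), the
first three mandatory; `location|C123` composites embed the focus resource
in the locator.

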