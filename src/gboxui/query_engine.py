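"""Translate interface selections into declarative queries and execute them.

Searches are conjunctive and at most two levels deep: a parent collection
(the one the interface is focused on) plus child collections linked to it
by collection-valued rules.  A single-node selection runs directly on the
parent; selections spanning linked collections are planned as parent plus
children, joined through the link statements.  Plans also serialize to
SPARQL 1.1 SELECT text over the flattened triple view of the store, where
each added child contributes a fixed number of extra triple patterns —
query structure grows linearly with the node count.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .errors import PlanError
from .s3db_store import KnowledgeBase, ResourceId, Rule


@dataclass(frozen=True)
class Filter:
    """One field condition: a rule on a collection compared against a literal."""

    node: ResourceId  # collection
    rule: ResourceId
    comparator: str  # "equals" | "contains"
    literal: str

    def matches(self, value: Optional[str]) -> bool:
        if value is None:
            return False
        if self.comparator == "equals":
            return value == self.literal
        if self.comparator == "contains":
            return self.literal.lower() in value.lower()
        raise PlanError(f"unknown comparator {self.comparator!r}")


@dataclass
class QueryPlan:
    parent: ResourceId
    children: list[ResourceId] = field(default_factory=list)
    filters: list[Filter] = field(default_factory=list)
    projection: list[ResourceId] = field(default_factory=list)  # rules to return

    @property
    def node_count(self) -> int:
        return 1 + len(self.children)


@dataclass
class RecordSet:
    """Query results: one row per matching parent item, sorted by identifier."""

    columns: list[str]
    rows: list[tuple[str, dict]] = field(default_factory=list)

    def identifiers(self) -> list[str]:
        return [ident for ident, _ in self.rows]

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["item"] + self.columns)
        for ident, values in self.rows:
            writer.writerow([ident] + [values.get(c, "") for c in self.columns])
        return buf.getvalue()


def _link_rule(kb: KnowledgeBase, parent: ResourceId, child: ResourceId) -> Rule:
    for rule in kb.link_rules(parent):
        if rule.object == child:
            return rule
    raise PlanError(f"no link rule from {parent} to {child}")


def build_plan(
    filters: Sequence[Filter],
    projection: Sequence[ResourceId],
    kb: KnowledgeBase,
    parent: Optional[ResourceId] = None,
) -> QueryPlan:
    """Derive the query plan from a form selection.

    Filters on a single collection give a one-level plan; filters spanning
    collections give a parent-plus-children plan (two levels).  The parent
    is the collection that links to every other referenced collection; a
    collection that cannot be linked to the parent is an error naming the
    missing link.  Projection rules may also pull in child collections.
    """
    filters = list(filters)
    projection = list(projection)
    for f in filters:
        rule = kb.rules.get(str(f.rule))
        if rule is None:
            raise PlanError(f"filter references unknown rule {f.rule}")
        if rule.subject != f.node:
            raise PlanError(
                f"rule {f.rule} is declared on {rule.subject}, not on {f.node}"
            )
    nodes: list[ResourceId] = []
    for f in filters:
        if f.node not in nodes:
            nodes.append(f.node)
    for rid in projection:
        rule = kb.rules.get(str(rid))
        if rule is None:
            raise PlanError(f"projection references unknown rule {rid}")
        if rule.subject not in nodes:
            nodes.append(rule.subject)

    if parent is None:
        if not nodes:
            raise PlanError("selection references no collection")
        if len(nodes) == 1:
            parent = nodes[0]
        else:
            candidates = [
                n
                for n in nodes
                if all(
                    m == n or any(r.object == m for r in kb.link_rules(n))
                    for m in nodes
                )
            ]
            if not candidates:
                raise PlanError(
                    "no collection links to all the others; "
                    f"selection spans {[str(n) for n in nodes]}"
                )
            parent = candidates[0]
    elif str(parent) not in kb.collections:
        raise PlanError(f"unknown parent collection {parent}")

    children: list[ResourceId] = []
    for n in nodes:
        if n == parent:
            continue
        _link_rule(kb, parent, n)  # raises naming the missing link
        children.append(n)
    return QueryPlan(parent=parent, children=children, filters=filters,
                     projection=projection)


# ---------------------------------------------------------------------------
# SPARQL emission
# ---------------------------------------------------------------------------

def _iri(kb: KnowledgeBase, rid: ResourceId) -> str:
    from . import vocab

    return f"<{vocab.resource_iri(str(kb.project), str(rid))}>"


def sparql_patterns(plan: QueryPlan, kb: KnowledgeBase) -> list[str]:
    """The triple patterns (and FILTER lines) of the WHERE clause.

    One enumerator pattern binds parent items through the parent
    collection's own rules; each parent filter adds one pattern; each child
    adds one link pattern plus one pattern per filter on it.  Filter-less
    children (projection only) are wrapped in OPTIONAL so they never
    constrain the parent set.
    """
    lines: list[str] = []
    parent_rules = " ".join(
        _iri(kb, r.id)
        for r in kb.literal_rules(plan.parent) + kb.link_rules(plan.parent)
    )
    lines.append(f"VALUES ?prule {{ {parent_rules} }}")
    lines.append("?parent ?prule ?pv .")
    # schema triples share the rule predicate; keep only item subjects
    lines.append('FILTER(REGEX(STR(?parent), "/I[0-9]+$"))')

    var = 0

    def add_filter(subject: str, f: Filter) -> None:
        nonlocal var
        if f.comparator == "equals":
            lines.append(f"{subject} {_iri(kb, f.rule)} {_sparql_str(f.literal)} .")
        else:
            var += 1
            v = f"?v{var}"
            lines.append(f"{subject} {_iri(kb, f.rule)} {v} .")
            lines.append(
                f"FILTER(CONTAINS(LCASE(STR({v})), {_sparql_str(f.literal.lower())}))"
            )

    for f in plan.filters:
        if f.node == plan.parent:
            add_filter("?parent", f)
    for i, child in enumerate(plan.children, start=1):
        link = _link_rule(kb, plan.parent, child)
        child_filters = [f for f in plan.filters if f.node == child]
        body = [f"?parent {_iri(kb, link.id)} ?c{i} ."]
        for f in child_filters:
            before = len(lines)
            add_filter(f"?c{i}", f)
            body.extend(lines[before:])
            del lines[before:]
        if child_filters:
            lines.extend(body)
        else:
            lines.append("OPTIONAL { " + " ".join(body) + " }")
    return lines


def _sparql_str(text: str) -> str:
    return '"' + text.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_sparql(plan: QueryPlan, kb: KnowledgeBase) -> str:
    """Emit a SPARQL 1.1 SELECT over the flattened triple vocabulary."""
    body = "\n  ".join(sparql_patterns(plan, kb))
    return f"SELECT DISTINCT ?parent WHERE {{\n  {body}\n}}"


def triple_pattern_count(plan: QueryPlan, kb: KnowledgeBase) -> int:
    """Number of triple patterns in the emitted query (FILTER/VALUES excluded)."""
    return sum(
        line.count(" .") for line in sparql_patterns(plan, kb)
        if not line.startswith(("FILTER", "VALUES"))
    )


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

def execute(plan: QueryPlan, kb: KnowledgeBase) -> RecordSet:
    """Run the plan: parent items whose own and linked-child statements
    satisfy every filter, with projected values, sorted by item identifier."""
    # value index: (item, rule) -> list of literal values / linked item ids
    values: dict[tuple[str, str], list] = {}
    for st in sorted(kb.statements.values(), key=lambda s: s.id.serial):
        values.setdefault((str(st.subject_item), str(st.rule)), []).append(st.value)

    def literals(item_id: ResourceId, rule_id: ResourceId) -> list[str]:
        return [
            v
            for v in values.get((str(item_id), str(rule_id)), [])
            if not isinstance(v, ResourceId)
        ]

    def passes(item_id: ResourceId, f: Filter) -> bool:
        vals = literals(item_id, f.rule)
        return any(f.matches(v) for v in vals)

    survivors = [i for i in kb.items_in(plan.parent)]
    for f in plan.filters:
        if f.node == plan.parent:
            survivors = [i for i in survivors if passes(i.id, f)]

    link_cache: dict[str, ResourceId] = {}
    for child in plan.children:
        child_filters = [f for f in plan.filters if f.node == child]
        if not child_filters:
            continue
        link = _link_rule(kb, plan.parent, child)
        link_cache[str(child)] = link.id
        ok_children = {
            str(i.id)
            for i in kb.items_in(child)
            if all(passes(i.id, f) for f in child_filters)
        }
        kept = []
        for item in survivors:
            linked = [
                str(v)
                for v in values.get((str(item.id), str(link.id)), [])
                if isinstance(v, ResourceId)
            ]
            if any(c in ok_children for c in linked):
                kept.append(item)
        survivors = kept

    columns = [kb.rules[str(r)].verb for r in plan.projection]
    rows = []
    for item in sorted(survivors, key=lambda i: i.identifier):
        projected = {}
        for rid in plan.projection:
            rule = kb.rules[str(rid)]
            if rule.subject == plan.parent:
                vals = literals(item.id, rule.id)
            else:
                link = _link_rule(kb, plan.parent, rule.subject)
                vals = []
                for v in values.get((str(item.id), str(link.id)), []):
                    if isinstance(v, ResourceId):
                        vals.extend(literals(v, rule.id))
            projected[rule.verb] = "; ".join(sorted(vals))
        rows.append((item.identifier, projected))
    return RecordSet(columns=columns, rows=rows)
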