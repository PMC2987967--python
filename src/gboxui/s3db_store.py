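"""Minimal in-process store for the S3DB data model.

The model partitions a knowledge base into a terminological component
(TBox: *rules*, schema edges between collections or from a collection to a
literal type) and an assertion component (ABox: *statements*, which
instantiate rules for concrete items).  Collections group items; a project
owns everything.  The two components never overlap: an element is either a
rule or a statement, and every statement instantiates exactly one rule.

Documents round-trip through Turtle/N3 via :func:`load_project` and
:func:`save_project`; tabular imports and single-statement mutations keep
the invariants checked; :func:`expand_triples` flattens the store into plain
subject-predicate-object triples for query execution.
"""

from __future__ import annotations

import copy
import csv
import io
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import yaml
from rdflib import Graph, Literal, RDF, URIRef

from . import vocab
from .errors import (
    ConfigurationError,
    FormatError,
    IntegrityError,
    NotFoundError,
)

LITERAL_TYPES = ("text", "date", "number")

_ID_RE = re.compile(r"^([PCIRS])(\d+)$")


@dataclass(frozen=True, order=True)
class ResourceId:
    """A typed identifier: one-letter kind tag plus a serial number.

    Kinds: P project, C collection, I item, R rule, S statement.  The
    rendered form is the tag immediately followed by digits, e.g. ``C12``.
    """

    prefix: str
    serial: int

    KINDS = frozenset("PCIRS")

    def __post_init__(self) -> None:
        if self.prefix not in self.KINDS:
            raise IntegrityError(f"unknown resource kind {self.prefix!r}")
        if self.serial < 0:
            raise IntegrityError(f"negative serial {self.serial}")

    def __str__(self) -> str:
        return f"{self.prefix}{self.serial}"

    @classmethod
    def parse(cls, text: str) -> "ResourceId":
        m = _ID_RE.match(text)
        if not m:
            raise FormatError(f"malformed resource id {text!r}")
        return cls(m.group(1), int(m.group(2)))


@dataclass
class Collection:
    id: ResourceId
    label: str
    parent_project: ResourceId


@dataclass
class Item:
    id: ResourceId
    collection: ResourceId
    identifier: str


@dataclass
class Rule:
    """TBox edge: subject collection --verb--> object collection or literal type."""

    id: ResourceId
    subject: ResourceId
    verb: str
    object: Union[ResourceId, str]  # collection id, or one of LITERAL_TYPES

    @property
    def is_link(self) -> bool:
        return isinstance(self.object, ResourceId)


@dataclass
class Statement:
    """ABox assertion: an item instantiates a rule with a value."""

    id: ResourceId
    subject_item: ResourceId
    rule: ResourceId
    value: Union[ResourceId, str]  # item id for link rules, literal otherwise

    @property
    def is_link(self) -> bool:
        return isinstance(self.value, ResourceId)


@dataclass
class StatementSpec:
    """Target of a mutation: (item, rule) plus the value to write."""

    item: ResourceId
    rule: ResourceId
    value: Union[ResourceId, str, None] = None
    statement: Optional[ResourceId] = None


@dataclass
class KnowledgeBase:
    project: ResourceId
    label: str = ""
    access_key: str = ""
    collections: dict[str, Collection] = field(default_factory=dict)
    items: dict[str, Item] = field(default_factory=dict)
    rules: dict[str, Rule] = field(default_factory=dict)
    statements: dict[str, Statement] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    _next_serial: int = 1

    # -- id allocation ----------------------------------------------------
    def new_id(self, prefix: str) -> ResourceId:
        """Allocate the next id; serials are monotone per project for determinism."""
        rid = ResourceId(prefix, self._next_serial)
        self._next_serial += 1
        return rid

    # -- construction helpers ---------------------------------------------
    def add_collection(self, label: str) -> Collection:
        if not label:
            raise IntegrityError("collection label must be non-empty")
        coll = Collection(self.new_id("C"), label, self.project)
        self.collections[str(coll.id)] = coll
        return coll

    def add_item(self, collection: ResourceId, identifier: str) -> Item:
        if str(collection) not in self.collections:
            raise NotFoundError(f"unknown collection {collection}")
        item = Item(self.new_id("I"), collection, identifier)
        self.items[str(item.id)] = item
        return item

    def add_rule(
        self, subject: ResourceId, verb: str, object: Union[ResourceId, str]
    ) -> Rule:
        if str(subject) not in self.collections:
            raise NotFoundError(f"unknown subject collection {subject}")
        if isinstance(object, ResourceId):
            if str(object) not in self.collections:
                raise NotFoundError(f"unknown object collection {object}")
        elif object not in LITERAL_TYPES:
            raise IntegrityError(
                f"rule object must be a collection or one of {LITERAL_TYPES}, got {object!r}"
            )
        rule = Rule(self.new_id("R"), subject, verb, object)
        self.rules[str(rule.id)] = rule
        return rule

    def add_statement(
        self, item: ResourceId, rule: ResourceId, value: Union[ResourceId, str]
    ) -> Statement:
        self._check_statement(item, rule, value)
        st = Statement(self.new_id("S"), item, rule, value)
        self.statements[str(st.id)] = st
        return st

    def _check_statement(
        self, item: ResourceId, rule_id: ResourceId, value: Union[ResourceId, str]
    ) -> None:
        rule = self.rules.get(str(rule_id))
        if rule is None:
            raise NotFoundError(f"unknown rule {rule_id}")
        it = self.items.get(str(item))
        if it is None:
            raise NotFoundError(f"unknown item {item}")
        if it.collection != rule.subject:
            raise IntegrityError(
                f"item {item} belongs to {it.collection}, "
                f"but rule {rule_id} is declared on {rule.subject}"
            )
        if rule.is_link:
            if not isinstance(value, ResourceId) or value.prefix != "I":
                raise IntegrityError(
                    f"rule {rule_id} links to {rule.object}; value must be an item"
                )
            target = self.items.get(str(value))
            if target is None:
                raise NotFoundError(f"unknown value item {value}")
            if target.collection != rule.object:
                raise IntegrityError(
                    f"value item {value} is not in collection {rule.object}"
                )
        elif isinstance(value, ResourceId):
            raise IntegrityError(
                f"rule {rule_id} takes a {rule.object} literal, not an item"
            )

    # -- lookups -----------------------------------------------------------
    def collection_by_label(self, label: str) -> Collection:
        for coll in self.collections.values():
            if coll.label == label:
                return coll
        raise NotFoundError(f"no collection labelled {label!r}")

    def rule_by_verb(self, verb: str) -> Rule:
        for rule in self.rules.values():
            if rule.verb == verb:
                return rule
        raise NotFoundError(f"no rule with verb {verb!r}")

    def items_in(self, collection: ResourceId) -> list[Item]:
        return [i for i in self.items.values() if i.collection == collection]

    def literal_rules(self, collection: ResourceId) -> list[Rule]:
        out = [
            r
            for r in self.rules.values()
            if r.subject == collection and not r.is_link
        ]
        return sorted(out, key=lambda r: r.id.serial)

    def link_rules(self, collection: ResourceId) -> list[Rule]:
        out = [r for r in self.rules.values() if r.subject == collection and r.is_link]
        return sorted(out, key=lambda r: r.id.serial)

    def statements_of(
        self, item: ResourceId, rule: Optional[ResourceId] = None
    ) -> list[Statement]:
        out = [
            s
            for s in self.statements.values()
            if s.subject_item == item and (rule is None or s.rule == rule)
        ]
        return sorted(out, key=lambda s: s.id.serial)

    def root_collection(self) -> Collection:
        """The collection with the most outgoing link rules (the aggregation root)."""
        if not self.collections:
            raise NotFoundError("knowledge base has no collections")
        best = max(
            self.collections.values(),
            key=lambda c: (len(self.link_rules(c.id)), -c.id.serial),
        )
        return best

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        """Re-check referential closure and the TBox/ABox partition."""
        bad: list[str] = []
        rule_ids = set(self.rules)
        stmt_ids = set(self.statements)
        overlap = rule_ids & stmt_ids
        if overlap:
            bad.append(f"elements in both TBox and ABox: {sorted(overlap)}")
        for coll in self.collections.values():
            if not coll.label:
                bad.append(f"{coll.id}: empty label")
            if coll.parent_project != self.project:
                bad.append(f"{coll.id}: foreign project {coll.parent_project}")
        for item in self.items.values():
            if str(item.collection) not in self.collections:
                bad.append(f"{item.id}: unknown collection {item.collection}")
        for rule in self.rules.values():
            if str(rule.subject) not in self.collections:
                bad.append(f"{rule.id}: unknown subject {rule.subject}")
            if rule.is_link and str(rule.object) not in self.collections:
                bad.append(f"{rule.id}: unknown object {rule.object}")
            if not rule.is_link and rule.object not in LITERAL_TYPES:
                bad.append(f"{rule.id}: bad literal type {rule.object!r}")
        for st in self.statements.values():
            try:
                self._check_statement(st.subject_item, st.rule, st.value)
            except (IntegrityError, NotFoundError) as exc:
                bad.append(f"{st.id}: {exc}")
        if bad:
            raise IntegrityError("; ".join(bad))


def new_project(label: str = "", access_key: str = "") -> KnowledgeBase:
    """Create an empty project; the project node itself takes serial 1."""
    kb = KnowledgeBase(ResourceId("P", 1), label=label, access_key=access_key)
    kb._next_serial = 2
    return kb


# ---------------------------------------------------------------------------
# RDF serialization
# ---------------------------------------------------------------------------

def _iri(kb: KnowledgeBase, rid: ResourceId) -> URIRef:
    return vocab.resource_iri(str(kb.project), str(rid))


def _rid_from_iri(node: URIRef) -> ResourceId:
    return ResourceId.parse(str(node).rsplit("/", 1)[-1])


def save_project(kb: KnowledgeBase, dialect: str = "turtle") -> str:
    """Serialize a knowledge base to Turtle or N3 text."""
    if dialect not in ("turtle", "n3"):
        raise FormatError(f"unknown dialect {dialect!r}")
    g = Graph()
    g.bind("gb", vocab.VOCAB)
    proj = _iri(kb, kb.project)
    g.add((proj, RDF.type, vocab.PROJECT))
    if kb.label:
        g.add((proj, vocab.LABEL, Literal(kb.label)))
    if kb.access_key:
        g.add((proj, vocab.ACCESS_KEY, Literal(kb.access_key)))
    for coll in kb.collections.values():
        node = _iri(kb, coll.id)
        g.add((node, RDF.type, vocab.COLLECTION))
        g.add((node, vocab.LABEL, Literal(coll.label)))
        g.add((node, vocab.IN_PROJECT, proj))
    for item in kb.items.values():
        node = _iri(kb, item.id)
        g.add((node, RDF.type, vocab.ITEM))
        g.add((node, vocab.IN_COLLECTION, _iri(kb, item.collection)))
        g.add((node, vocab.IDENTIFIER, Literal(item.identifier)))
    for rule in kb.rules.values():
        node = _iri(kb, rule.id)
        g.add((node, RDF.type, vocab.RULE))
        g.add((node, vocab.SUBJECT, _iri(kb, rule.subject)))
        g.add((node, vocab.VERB, Literal(rule.verb)))
        if rule.is_link:
            g.add((node, vocab.OBJECT, _iri(kb, rule.object)))
        else:
            g.add((node, vocab.VALUE, Literal(rule.object)))
    for st in kb.statements.values():
        node = _iri(kb, st.id)
        g.add((node, RDF.type, vocab.STATEMENT))
        g.add((node, vocab.SUBJECT, _iri(kb, st.subject_item)))
        g.add((node, vocab.INSTANCE_OF, _iri(kb, st.rule)))
        if st.is_link:
            g.add((node, vocab.OBJECT, _iri(kb, st.value)))
        else:
            g.add((node, vocab.VALUE, Literal(st.value)))
    return g.serialize(format=dialect)


def load_project(source: str, dialect: str = "turtle") -> KnowledgeBase:
    """Parse a Turtle/N3 project document into a validated KnowledgeBase.

    Unknown predicates are collected in ``kb.warnings`` rather than dropped
    silently.  Parse failures raise :class:`FormatError` with line info when
    the parser reports it; invariant violations raise :class:`IntegrityError`
    naming the offending ids.
    """
    if dialect not in ("turtle", "n3"):
        raise FormatError(f"unknown dialect {dialect!r}")
    g = Graph()
    try:
        g.parse(data=source, format=dialect)
    except Exception as exc:  # rdflib's BadSyntax carries position info
        raise FormatError(f"cannot parse {dialect} document: {exc}") from exc

    projects = sorted(g.subjects(RDF.type, vocab.PROJECT))
    if not projects:
        if len(g) == 0:
            return new_project()
        raise IntegrityError("document has triples but no project node")
    if len(projects) > 1:
        raise IntegrityError(f"multiple project nodes: {[str(p) for p in projects]}")
    proj_node = projects[0]
    kb = KnowledgeBase(_rid_from_iri(proj_node))
    kb.label = str(g.value(proj_node, vocab.LABEL) or "")
    kb.access_key = str(g.value(proj_node, vocab.ACCESS_KEY) or "")

    def nodes_of(cls) -> list[URIRef]:
        return sorted(g.subjects(RDF.type, cls), key=lambda n: _rid_from_iri(n).serial)

    for node in nodes_of(vocab.COLLECTION):
        rid = _rid_from_iri(node)
        label = g.value(node, vocab.LABEL)
        if label is None:
            raise IntegrityError(f"{rid}: collection without label")
        kb.collections[str(rid)] = Collection(rid, str(label), kb.project)
    for node in nodes_of(vocab.ITEM):
        rid = _rid_from_iri(node)
        coll = g.value(node, vocab.IN_COLLECTION)
        if coll is None:
            raise IntegrityError(f"{rid}: item without collection")
        ident = str(g.value(node, vocab.IDENTIFIER) or "")
        kb.items[str(rid)] = Item(rid, _rid_from_iri(coll), ident)
    for node in nodes_of(vocab.RULE):
        rid = _rid_from_iri(node)
        subj = g.value(node, vocab.SUBJECT)
        verb = g.value(node, vocab.VERB)
        obj = g.value(node, vocab.OBJECT)
        lit = g.value(node, vocab.VALUE)
        if subj is None or verb is None or (obj is None) == (lit is None):
            raise IntegrityError(
                f"{rid}: rule needs subject, verb and exactly one of "
                "object (collection) or value (literal type)"
            )
        target: Union[ResourceId, str]
        target = _rid_from_iri(obj) if obj is not None else str(lit)
        kb.rules[str(rid)] = Rule(rid, _rid_from_iri(subj), str(verb), target)
    for node in nodes_of(vocab.STATEMENT):
        rid = _rid_from_iri(node)
        subj = g.value(node, vocab.SUBJECT)
        rule = g.value(node, vocab.INSTANCE_OF)
        obj = g.value(node, vocab.OBJECT)
        lit = g.value(node, vocab.VALUE)
        if subj is None or rule is None or (obj is None) == (lit is None):
            raise IntegrityError(
                f"{rid}: statement needs subject, instanceOf and exactly one of "
                "object (item) or value (literal)"
            )
        value: Union[ResourceId, str]
        value = _rid_from_iri(obj) if obj is not None else str(lit)
        kb.statements[str(rid)] = Statement(
            rid, _rid_from_iri(subj), _rid_from_iri(rule), value
        )

    for _, pred, _ in g:
        if pred != RDF.type and pred not in vocab.KNOWN_PREDICATES:
            msg = f"unknown predicate {pred}"
            if msg not in kb.warnings:
                kb.warnings.append(msg)

    serials = [kb.project.serial] + [
        ResourceId.parse(k).serial
        for part in (kb.collections, kb.items, kb.rules, kb.statements)
        for k in part
    ]
    kb._next_serial = max(serials) + 1
    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# Tabular import
# ---------------------------------------------------------------------------

def import_tabular(
    kb: KnowledgeBase,
    table: str,
    mapping: Union[str, Mapping],
    delimiter: Optional[str] = None,
) -> KnowledgeBase:
    """Import delimited text into a copy of ``kb``, one statement per cell.

    ``mapping`` is a YAML document (or an equivalent dict) with keys:

    * ``key_column`` — the column whose value identifies/creates the subject
      item in the root collection;
    * ``root`` — the root collection id the subject items belong to;
    * ``columns`` — column name → rule id.

    One literal statement is created per non-empty mapped cell.  When a
    mapped rule lives on a child collection, a per-row child item is created
    (once) and linked to the root item through the root→child rule.  The
    import is idempotent: statements are keyed on (item, rule, value), so
    re-importing identical rows creates nothing.  Empty cells produce no
    statement at all.
    """
    if isinstance(mapping, str):
        mapping = yaml.safe_load(mapping) or {}
    key_column = mapping.get("key_column")
    if not key_column:
        raise ConfigurationError("mapping must designate a key_column")
    columns: Mapping[str, str] = mapping.get("columns") or {}
    root_id = ResourceId.parse(str(mapping["root"])) if "root" in mapping else None

    out = copy.deepcopy(kb)
    if root_id is None:
        root_id = out.root_collection().id
    if str(root_id) not in out.collections:
        raise NotFoundError(f"unknown root collection {root_id}")

    if delimiter is None:
        header = table.splitlines()[0] if table.strip() else ""
        delimiter = "\t" if "\t" in header else ","
    reader = csv.DictReader(io.StringIO(table), delimiter=delimiter)
    rows = list(reader)
    if rows and key_column not in (reader.fieldnames or []):
        raise ConfigurationError(f"key column {key_column!r} not present in table")

    col_rules: dict[str, Rule] = {}
    for col, rule_id in columns.items():
        rule = out.rules.get(str(rule_id))
        if rule is None:
            raise NotFoundError(f"mapped rule {rule_id} for column {col!r} not found")
        if rule.is_link:
            raise IntegrityError(
                f"column {col!r} maps to link rule {rule.id}; only literal rules importable"
            )
        col_rules[col] = rule

    existing = {
        (str(s.subject_item), str(s.rule), str(s.value))
        for s in out.statements.values()
    }
    root_items = {i.identifier: i for i in out.items_in(root_id)}
    mismatches: list[int] = []

    for rownum, row in enumerate(rows, start=2):  # header is line 1
        key = (row.get(key_column) or "").strip()
        if not key:
            mismatches.append(rownum)
            continue
        root_item = root_items.get(key)
        if root_item is None:
            root_item = out.add_item(root_id, key)
            root_items[key] = root_item
        child_items: dict[str, Item] = {}
        for col, rule in col_rules.items():
            value = (row.get(col) or "").strip()
            if not value:
                continue  # absence, not empty string
            if rule.subject == root_id:
                subject = root_item
            else:
                ckey = str(rule.subject)
                subject = child_items.get(ckey)
                if subject is None:
                    subject = _linked_child(out, root_item, rule.subject, create=True)
                    child_items[ckey] = subject
            sig = (str(subject.id), str(rule.id), value)
            if sig not in existing:
                out.add_statement(subject.id, rule.id, value)
                existing.add(sig)
    if mismatches:
        raise IntegrityError(f"rows with empty key column: {mismatches}")
    out.validate()
    return out


def _linked_child(
    kb: KnowledgeBase, root_item: Item, child_coll: ResourceId, create: bool
) -> Item:
    """Find (or create+link) the per-root-item child item in ``child_coll``."""
    links = [
        r
        for r in kb.link_rules(root_item.collection)
        if r.object == child_coll
    ]
    if not links:
        raise IntegrityError(
            f"no link rule from {root_item.collection} to {child_coll}"
        )
    link = links[0]
    for st in kb.statements_of(root_item.id, link.id):
        if isinstance(st.value, ResourceId):
            return kb.items[str(st.value)]
    if not create:
        raise NotFoundError(
            f"item {root_item.id} has no linked child in {child_coll}"
        )
    coll_label = kb.collections[str(child_coll)].label
    child = kb.add_item(child_coll, f"{root_item.identifier}-{coll_label}")
    kb.add_statement(root_item.id, link.id, child.id)
    return child


# ---------------------------------------------------------------------------
# Mutation
# ---------------------------------------------------------------------------

def mutate(kb: KnowledgeBase, op: str, spec: StatementSpec) -> KnowledgeBase:
    """Insert, update or delete a single statement; returns a new KnowledgeBase.

    Updates and deletes target the statement named in ``spec.statement`` or,
    failing that, the unique statement on (item, rule).  All invariants are
    re-checked before returning.
    """
    if op not in ("insert", "update", "delete"):
        raise ConfigurationError(f"unknown mutation op {op!r}")
    out = copy.deepcopy(kb)
    if op == "insert":
        if spec.value is None:
            raise ConfigurationError("insert requires a value")
        out.add_statement(spec.item, spec.rule, spec.value)
    else:
        target = _find_statement(out, spec)
        if op == "update":
            if spec.value is None:
                raise ConfigurationError("update requires a value")
            out._check_statement(target.subject_item, target.rule, spec.value)
            out.statements[str(target.id)] = Statement(
                target.id, target.subject_item, target.rule, spec.value
            )
        else:
            del out.statements[str(target.id)]
    out.validate()
    return out


def _find_statement(kb: KnowledgeBase, spec: StatementSpec) -> Statement:
    if spec.statement is not None:
        st = kb.statements.get(str(spec.statement))
        if st is None:
            raise NotFoundError(f"statement {spec.statement} not found")
        return st
    matches = kb.statements_of(spec.item, spec.rule)
    if not matches:
        raise NotFoundError(
            f"no statement on item {spec.item} under rule {spec.rule}"
        )
    return matches[0]


# ---------------------------------------------------------------------------
# Triple expansion
# ---------------------------------------------------------------------------

def expand_triples(kb: KnowledgeBase) -> Graph:
    """Flatten the store to plain dyadic predicates.

    Exactly one triple per rule (schema: subject collection, rule IRI as
    predicate, object collection or literal type) and one per statement
    (assertion: item, rule IRI, value).  The result is a queryable RDF graph
    whose size equals ``len(kb.rules) + len(kb.statements)``.
    """
    g = Graph()
    g.bind("gb", vocab.VOCAB)
    for rule in kb.rules.values():
        obj = (
            _iri(kb, rule.object)
            if rule.is_link
            else Literal(rule.object)
        )
        g.add((_iri(kb, rule.subject), _iri(kb, rule.id), obj))
    for st in kb.statements.values():
        obj = _iri(kb, st.value) if st.is_link else Literal(st.value)
        g.add((_iri(kb, st.subject_item), _iri(kb, st.rule), obj))
    return g


def triples_as_text(g: Graph) -> str:
    """Deterministic (sorted) N-Triples rendering of an expanded graph."""
    return "".join(sorted(line + "\n" for line in g.serialize(format="nt").splitlines() if line.strip()))
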