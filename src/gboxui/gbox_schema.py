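"""The fixed graphic model: 11 GUI actions crossed with 5 GUI-rule slots.

A GUI-rule instance fills five slots — domain, range, action, trigger,
value — where *domain* holds the id of the schema rule that commands the
action, *range* the rule that receives it, *trigger* the literal tested
against the data, and *value* the literal written into the range when the
test holds.  The action registry is closed: exactly eleven action types
exist and a twelfth cannot be registered.

Six action names are fixed by the model (hasSubCollections, hasText,
hasDate, hasFormula, hasFieldInactive, hasOptions).  The remaining five —
hasTab, hasLabel, hasHidden, hasLink, hasTestValue — are defined by this
package to cover tab creation, labelling, hiding, cross-references and the
trigger-test behaviour; their names are implementation-defined, not part of
the published model.
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field
from typing import Optional, Sequence

from rdflib import Graph, Literal, RDF, URIRef

from . import vocab
from .errors import FormatError, SchemaError
from .s3db_store import ResourceId

GUI_RULE_SLOTS = ("domain", "range", "action", "trigger", "value")
REGISTRY_CAPACITY = 11

PAPER_NAMED_ACTIONS = (
    "hasSubCollections",
    "hasText",
    "hasDate",
    "hasFormula",
    "hasFieldInactive",
    "hasOptions",
)


@dataclass(frozen=True)
class ActionType:
    """One of the 11 graphic behaviours.

    ``slot_profile`` lists which of the optional slots (range, trigger,
    value) an instance of this action must fill — its row of the 11×5
    action/slot cross-tabulation.  Domain is mandatory for every action.
    """

    name: str
    component_kind: str
    requires_trigger: bool
    requires_value: bool
    slot_profile: frozenset[str]

    def __post_init__(self) -> None:
        extra = self.slot_profile - {"range", "trigger", "value"}
        if extra:
            raise SchemaError(f"{self.name}: unknown slots {sorted(extra)}")
        if self.requires_trigger != ("trigger" in self.slot_profile):
            raise SchemaError(f"{self.name}: requires_trigger inconsistent with profile")
        if self.requires_value != ("value" in self.slot_profile):
            raise SchemaError(f"{self.name}: requires_value inconsistent with profile")


class ActionRegistry:
    """Closed registry of action types; capped at exactly eleven entries."""

    def __init__(self) -> None:
        self._actions: dict[str, ActionType] = {}

    def register(self, action: ActionType) -> None:
        if action.name in self._actions:
            raise SchemaError(f"action {action.name!r} already registered")
        if len(self._actions) >= REGISTRY_CAPACITY:
            raise SchemaError(
                f"registry is closed at {REGISTRY_CAPACITY} actions; "
                f"cannot register {action.name!r}"
            )
        self._actions[action.name] = action

    def lookup(self, name: str) -> ActionType:
        try:
            return self._actions[name]
        except KeyError:
            raise SchemaError(f"unknown action {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._actions

    def __len__(self) -> int:
        return len(self._actions)

    def __iter__(self):
        return iter(self._actions.values())

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._actions)


def _action(name, kind, profile=()):
    profile = frozenset(profile)
    return ActionType(
        name,
        kind,
        requires_trigger="trigger" in profile,
        requires_value="value" in profile,
        slot_profile=profile,
    )


def default_registry() -> ActionRegistry:
    """The standard registry: 6 model-named actions plus 5 package-defined ones."""
    reg = ActionRegistry()
    for action in (
        _action("hasSubCollections", "sub_tabs"),
        _action("hasText", "text_field"),
        _action("hasDate", "date_field"),
        _action("hasFormula", "formula_field", ("value",)),
        _action("hasFieldInactive", "inactive_field"),
        _action("hasOptions", "options_field", ("value",)),
        # package-defined complements (not part of the published six):
        _action("hasTab", "tab"),
        _action("hasLabel", "label", ("value",)),
        _action("hasHidden", "hidden_field"),
        _action("hasLink", "link_field", ("range",)),
        _action("hasTestValue", "test", ("range", "trigger", "value")),
    ):
        reg.register(action)
    return reg


@dataclass(frozen=True)
class GuiRuleInstance:
    """One filled 5-slot descriptor binding an action to domain rules."""

    domain: Optional[ResourceId]
    action: str
    range: Optional[ResourceId] = None
    trigger: Optional[str] = None
    value: Optional[str] = None

    def present_slots(self) -> frozenset[str]:
        out = set()
        if self.domain is not None:
            out.add("domain")
        if self.range is not None:
            out.add("range")
        if self.trigger is not None:
            out.add("trigger")
        if self.value is not None:
            out.add("value")
        return frozenset(out)

    def validate(self, registry: ActionRegistry) -> None:
        action = registry.lookup(self.action)
        present = self.present_slots()
        expected = frozenset({"domain"}) | action.slot_profile
        if "domain" not in present:
            raise SchemaError(f"instance of {self.action!r} lacks mandatory domain slot")
        if present != expected:
            raise SchemaError(
                f"instance of {self.action!r} fills slots {sorted(present)}, "
                f"but the action's profile is {sorted(expected)}"
            )


@dataclass
class GBoxSpec:
    """A graphic-descriptor project: the action registry plus ordered instances."""

    project: ResourceId
    actions: ActionRegistry
    rules: list[GuiRuleInstance] = field(default_factory=list)
    label: str = ""
    access_key: str = ""

    def validate(self) -> None:
        if len(self.actions) != REGISTRY_CAPACITY:
            raise SchemaError(
                f"registry holds {len(self.actions)} actions, expected {REGISTRY_CAPACITY}"
            )
        for inst in self.rules:
            inst.validate(self.actions)


# ---------------------------------------------------------------------------
# RDF round trip
# ---------------------------------------------------------------------------

def serialize_gbox(spec: GBoxSpec, dialect: str = "turtle") -> str:
    """Write a GBox project as Turtle/N3 using the store vocabulary.

    Instances carry an explicit order index so document order (which drives
    display order) survives the round trip.
    """
    if dialect not in ("turtle", "n3"):
        raise FormatError(f"unknown dialect {dialect!r}")
    g = Graph()
    g.bind("gb", vocab.VOCAB)
    proj = vocab.resource_iri(str(spec.project), str(spec.project))
    g.add((proj, RDF.type, vocab.PROJECT))
    if spec.label:
        g.add((proj, vocab.LABEL, Literal(spec.label)))
    if spec.access_key:
        g.add((proj, vocab.ACCESS_KEY, Literal(spec.access_key)))
    for idx, inst in enumerate(spec.rules):
        node = vocab.resource_iri(str(spec.project), f"G{idx + 1}")
        g.add((node, RDF.type, vocab.GUI_RULE))
        g.add((node, vocab.ORDER, Literal(idx)))
        g.add((node, vocab.DOMAIN, Literal(str(inst.domain))))
        g.add((node, vocab.ACTION, Literal(inst.action)))
        if inst.range is not None:
            g.add((node, vocab.RANGE, Literal(str(inst.range))))
        if inst.trigger is not None:
            g.add((node, vocab.TRIGGER, Literal(inst.trigger)))
        if inst.value is not None:
            g.add((node, vocab.VALUE, Literal(inst.value)))
    return g.serialize(format=dialect)


def parse_gbox(
    source: str, registry: Optional[ActionRegistry] = None, dialect: str = "turtle"
) -> GBoxSpec:
    """Parse a GBox project document; every violation is reported, none skipped."""
    if registry is None:
        registry = default_registry()
    if dialect not in ("turtle", "n3"):
        raise FormatError(f"unknown dialect {dialect!r}")
    g = Graph()
    try:
        g.parse(data=source, format=dialect)
    except Exception as exc:
        raise FormatError(f"cannot parse {dialect} document: {exc}") from exc

    projects = sorted(g.subjects(RDF.type, vocab.PROJECT))
    if projects:
        proj_node = projects[0]
        project = ResourceId.parse(str(proj_node).rsplit("/", 1)[-1])
        label = str(g.value(proj_node, vocab.LABEL) or "")
        key = str(g.value(proj_node, vocab.ACCESS_KEY) or "")
    else:
        project, label, key = ResourceId("P", 1), "", ""

    def order_key(node):
        val = g.value(node, vocab.ORDER)
        return (int(val) if val is not None else 0, str(node))

    instances: list[GuiRuleInstance] = []
    problems: list[str] = []
    for node in sorted(g.subjects(RDF.type, vocab.GUI_RULE), key=order_key):
        name = str(node).rsplit("/", 1)[-1]
        action = g.value(node, vocab.ACTION)
        domain = g.value(node, vocab.DOMAIN)
        if action is None or str(action) not in registry:
            problems.append(f"{name}: unknown or missing action {action}")
            continue
        if domain is None:
            problems.append(f"{name}: missing mandatory domain slot")
            continue
        rng = g.value(node, vocab.RANGE)
        trig = g.value(node, vocab.TRIGGER)
        val = g.value(node, vocab.VALUE)
        inst = GuiRuleInstance(
            domain=ResourceId.parse(str(domain)),
            action=str(action),
            range=ResourceId.parse(str(rng)) if rng is not None else None,
            trigger=str(trig) if trig is not None else None,
            value=str(val) if val is not None else None,
        )
        try:
            inst.validate(registry)
        except SchemaError as exc:
            problems.append(f"{name}: {exc}")
            continue
        instances.append(inst)
    if problems:
        raise SchemaError("; ".join(problems))
    return GBoxSpec(project=project, actions=registry, rules=instances,
                    label=label, access_key=key)


# ---------------------------------------------------------------------------
# Triple view
# ---------------------------------------------------------------------------

def _compose(base: str, extra: Optional[str]) -> str:
    """Reversible composite encoding: base, optionally '|'-joined with extra."""
    out = urllib.parse.quote(base, safe="")
    if extra is not None:
        out += "|" + urllib.parse.quote(extra, safe="")
    return out


def _decompose(text: str) -> tuple[str, Optional[str]]:
    if "|" in text:
        base, extra = text.split("|", 1)
        return urllib.parse.unquote(base), urllib.parse.unquote(extra)
    return urllib.parse.unquote(text), None


def gbox_to_triples(spec: GBoxSpec) -> list[tuple[str, str, str]]:
    """Render instances as triples: subject = domain (plus trigger for test
    actions), predicate = action, object = range (plus value).

    The composite encoding is reversible; see :func:`triples_to_gbox`.  The
    list preserves document order so the inverse is exact.
    """
    spec.validate()
    triples = []
    for inst in spec.rules:
        subject = _compose(str(inst.domain), inst.trigger)
        obj = _compose(str(inst.range) if inst.range is not None else "", inst.value)
        triples.append((subject, inst.action, obj))
    return triples


def triples_to_gbox(
    triples: Sequence[tuple[str, str, str]],
    registry: Optional[ActionRegistry] = None,
    project: Optional[ResourceId] = None,
) -> GBoxSpec:
    """Inverse of :func:`gbox_to_triples`."""
    if registry is None:
        registry = default_registry()
    rules = []
    for subject, action, obj in triples:
        dom, trig = _decompose(subject)
        rng, val = _decompose(obj)
        rules.append(
            GuiRuleInstance(
                domain=ResourceId.parse(dom),
                action=action,
                range=ResourceId.parse(rng) if rng else None,
                trigger=trig,
                value=val,
            )
        )
    spec = GBoxSpec(project=project or ResourceId("P", 1), actions=registry, rules=rules)
    spec.validate()
    return spec
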