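"""Four-stage autonomous interface assembly.

The pipeline mirrors the flow of the original browser application:
(A) load the two sources, (B) split domain description from graphic layout,
(C) translate each into a document model, (D) merge them into the final
interface object.  Stage D is implemented here: :func:`default_layout`
derives the GBox-absent interface purely from the topology of the domain
schema (collections become tabs, literal rules become rows), and
:func:`assemble` overlays graphic-rule instances on top of it.  The result
is a :class:`UIDocument` with a deterministic canonical-JSON serialization,
renderable to static HTML5 or JSON.

Trigger semantics: a test-action instance carries (domain rule, trigger,
range rule, value).  When a concrete item's statement under the domain rule
equals the trigger, the configured value is written into the component
bound to the range rule; otherwise the component is untouched.  Formula
fields re-evaluate their arithmetic expression over sibling field values
each time an item is viewed.
"""

from __future__ import annotations

import ast
import dataclasses
import html
import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import NotFoundError, UsageError
from .gbox_schema import GBoxSpec, GuiRuleInstance
from .s3db_store import KnowledgeBase, ResourceId

log = logging.getLogger(__name__)


@dataclass
class UIComponent:
    kind: str
    label: str
    bound_rule: Optional[ResourceId] = None
    widget_config: dict = field(default_factory=dict)
    provenance: str = "default"


@dataclass
class Tab:
    collection: ResourceId
    label: str
    components: list[UIComponent] = field(default_factory=list)
    sub_tabs: list["Tab"] = field(default_factory=list)
    provenance: str = "default"


@dataclass
class TriggerBinding:
    """A pending test: if item[domain] == trigger then range.value := value."""

    domain: ResourceId
    range: ResourceId
    trigger: str
    value: str
    provenance: str


@dataclass
class UIDocument:
    root_collection: ResourceId
    tabs: list[Tab] = field(default_factory=list)
    triggers: list[TriggerBinding] = field(default_factory=list)

    def all_components(self) -> list[UIComponent]:
        out: list[UIComponent] = []

        def walk(tab: Tab) -> None:
            out.extend(tab.components)
            for sub in tab.sub_tabs:
                walk(sub)

        for tab in self.tabs:
            walk(tab)
        return out

    def component_for(self, rule: ResourceId) -> Optional[UIComponent]:
        for comp in self.all_components():
            if comp.bound_rule == rule:
                return comp
        return None

    def to_canonical_json(self) -> str:
        """Byte-stable serialization: sorted keys, UTF-8, LF, trailing newline."""

        def encode(obj):
            if isinstance(obj, ResourceId):
                return str(obj)
            if isinstance(obj, (UIComponent, Tab, TriggerBinding, UIDocument)):
                return {
                    f.name: encode(getattr(obj, f.name))
                    for f in dataclasses.fields(obj)
                }
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [encode(v) for v in obj]
            return obj

        return (
            json.dumps(encode(self), sort_keys=True, ensure_ascii=False, indent=2)
            + "\n"
        )


# ---------------------------------------------------------------------------
# Stage D1: default layout from domain topology alone
# ---------------------------------------------------------------------------

def default_layout(kb: KnowledgeBase, target: ResourceId) -> UIDocument:
    """GBox-absent assembly: tab structure from the schema topology only.

    The target collection is the aggregation root.  Each collection it links
    to through a collection-valued rule becomes a tab (one hop by default;
    deeper nesting is a GBox concern, via hasSubCollections).  Within each
    tab, every literal-valued rule becomes one row component.
    """
    coll = kb.collections.get(str(target))
    if coll is None:
        raise NotFoundError(f"unknown target collection {target}")

    def make_tab(collection_id: ResourceId) -> Tab:
        c = kb.collections[str(collection_id)]
        tab = Tab(collection=c.id, label=c.label)
        for rule in kb.literal_rules(c.id):
            tab.components.append(
                UIComponent(
                    kind="row",
                    label=rule.verb,
                    bound_rule=rule.id,
                    widget_config={"value_type": rule.object, "active": True},
                )
            )
        return tab

    root_tab = make_tab(coll.id)
    for link in kb.link_rules(coll.id):
        root_tab.sub_tabs.append(make_tab(link.object))
    return UIDocument(root_collection=coll.id, tabs=[root_tab])


# ---------------------------------------------------------------------------
# Stage D2: overlay GBox instances
# ---------------------------------------------------------------------------

def assemble(
    kb: KnowledgeBase, gbox: Optional[GBoxSpec], target: ResourceId
) -> UIDocument:
    """Merge domain structure and graphic rules into the interface model.

    With no GBox this is exactly :func:`default_layout`.  Otherwise each
    instance, in document order, replaces or augments the default component
    bound to its domain rule.  Instances whose domain rule has no component
    (or tab) are logged and skipped, never fatal.  When several instances
    target the same component the last writer wins, with a warning.
    """
    doc = default_layout(kb, target)
    if gbox is None:
        return doc
    gbox.validate()

    customized: dict[str, str] = {}  # rule id -> provenance of last writer
    for idx, inst in enumerate(gbox.rules):
        provenance = f"gui-rule-{idx + 1}"
        action = gbox.actions.lookup(inst.action)
        if action.requires_trigger:
            doc.triggers.append(
                TriggerBinding(
                    domain=inst.domain,
                    range=inst.range,
                    trigger=inst.trigger,
                    value=inst.value,
                    provenance=provenance,
                )
            )
            continue
        rule = kb.rules.get(str(inst.domain))
        if rule is None:
            log.warning("%s: domain rule %s not in project; skipped",
                        provenance, inst.domain)
            continue
        if action.component_kind in ("sub_tabs", "tab"):
            _apply_structural(doc, kb, inst, action.component_kind, provenance)
            continue
        comp = doc.component_for(inst.domain)
        if comp is None:
            log.warning("%s: no component bound to rule %s; skipped",
                        provenance, inst.domain)
            continue
        prev = customized.get(str(inst.domain))
        if prev is not None:
            log.warning("%s overrides %s on rule %s (last writer wins)",
                        provenance, prev, inst.domain)
        customized[str(inst.domain)] = provenance
        _apply_component(comp, inst, action.component_kind, provenance)
    return doc


def _apply_structural(doc, kb, inst, kind, provenance) -> None:
    rule = kb.rules[str(inst.domain)]
    if not rule.is_link:
        log.warning("%s: %s needs a collection-valued domain rule; skipped",
                    provenance, inst.action)
        return
    if kind == "tab":
        for tab in doc.tabs[0].sub_tabs:
            if tab.collection == rule.object:
                tab.provenance = provenance
                return
        log.warning("%s: no tab for collection %s; skipped", provenance, rule.object)
        return
    # sub_tabs: augment the root tab with a navigation component; the default
    # tab for the child collection is kept (augmentation never removes tabs).
    child = kb.collections[str(rule.object)]
    doc.tabs[0].components.append(
        UIComponent(
            kind="sub_tabs",
            label=child.label,
            bound_rule=rule.id,
            widget_config={"target_collection": str(child.id), "active": True},
            provenance=provenance,
        )
    )


def _apply_component(comp: UIComponent, inst: GuiRuleInstance, kind: str,
                     provenance: str) -> None:
    comp.provenance = provenance
    if kind == "label":
        comp.label = inst.value
        return
    if kind == "hidden_field":
        comp.kind = "hidden_field"
        comp.widget_config["hidden"] = True
        return
    comp.kind = kind
    if kind == "formula_field":
        comp.widget_config["formula"] = inst.value
    elif kind == "options_field":
        comp.widget_config["options"] = inst.value.split("|")
    elif kind == "inactive_field":
        comp.widget_config["active"] = False
    elif kind == "date_field":
        comp.widget_config["date_format"] = "YYYY-MM-DD"
    elif kind == "link_field":
        comp.widget_config["target_rule"] = str(inst.range)


# ---------------------------------------------------------------------------
# View: triggers, values and formulas for a concrete item
# ---------------------------------------------------------------------------

def _resolve_value(kb: KnowledgeBase, root_item, rule) -> Optional[str]:
    """The item's value under a rule, following one link hop when the rule
    lives on a child collection."""
    if rule.subject == root_item.collection:
        subject = root_item
    else:
        subject = None
        for link in kb.link_rules(root_item.collection):
            if link.object == rule.subject:
                for st in kb.statements_of(root_item.id, link.id):
                    if isinstance(st.value, ResourceId):
                        subject = kb.items[str(st.value)]
                        break
            if subject is not None:
                break
        if subject is None:
            return None
    stmts = kb.statements_of(subject.id, rule.id)
    for st in stmts:
        if not isinstance(st.value, ResourceId):
            return st.value
    return None


def apply_triggers(ui: UIDocument, kb: KnowledgeBase, item: ResourceId) -> UIDocument:
    """Populate the interface for one item: field values, test actions, formulas.

    Returns a new document; the input is not modified.  Missing statements
    simply fail the test (no error).  Components whose value is absent are
    flagged inactive for display.
    """
    it = kb.items.get(str(item))
    if it is None:
        raise NotFoundError(f"unknown item {item}")
    out = _clone(ui)

    for comp in out.all_components():
        if comp.bound_rule is None:
            continue
        rule = kb.rules.get(str(comp.bound_rule))
        if rule is None or rule.is_link:
            continue
        value = _resolve_value(kb, it, rule)
        if value is None:
            comp.widget_config["active"] = False
        else:
            comp.widget_config["value"] = value

    for trig in out.triggers:
        rule = kb.rules.get(str(trig.domain))
        if rule is None:
            continue
        observed = _resolve_value(kb, it, rule)
        if observed == trig.trigger:  # exact, case-sensitive
            comp = out.component_for(trig.range)
            if comp is not None:
                comp.widget_config["value"] = trig.value
                comp.provenance = trig.provenance

    # formulas last, so triggered values participate
    siblings = {
        comp.label: comp.widget_config.get("value")
        for comp in out.all_components()
    }
    for comp in out.all_components():
        formula = comp.widget_config.get("formula")
        if formula:
            result = evaluate_formula(formula, siblings)
            if result is not None:
                comp.widget_config["value"] = _format_number(result)
    return out


def _clone(ui: UIDocument) -> UIDocument:
    import copy

    return copy.deepcopy(ui)


def _format_number(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


def evaluate_formula(formula: str, bindings: dict) -> Optional[float]:
    """Evaluate an arithmetic expression over sibling field references.

    References are written ``{field label}``; the grammar is + - * / and
    parentheses.  Returns None when any referenced value is missing or
    non-numeric (the field then stays blank, like any other missing value).
    """
    expr = formula
    for label, value in sorted(bindings.items(), key=lambda kv: -len(kv[0])):
        token = "{" + label + "}"
        if token in expr:
            if value is None:
                return None
            try:
                expr = expr.replace(token, repr(float(value)))
            except (TypeError, ValueError):
                return None
    if "{" in expr:
        return None
    try:
        tree = ast.parse(expr, mode="eval")
    except SyntaxError:
        return None
    return _eval_node(tree.body)


_BIN_OPS = {
    ast.Add: lambda a, b: a + b,
    ast.Sub: lambda a, b: a - b,
    ast.Mult: lambda a, b: a * b,
    ast.Div: lambda a, b: a / b,
}


def _eval_node(node) -> Optional[float]:
    if isinstance(node, ast.Constant) and isinstance(node.value, (int, float)):
        return float(node.value)
    if isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        val = _eval_node(node.operand)
        if val is None:
            return None
        return -val if isinstance(node.op, ast.USub) else val
    if isinstance(node, ast.BinOp) and type(node.op) in _BIN_OPS:
        left, right = _eval_node(node.left), _eval_node(node.right)
        if left is None or right is None:
            return None
        try:
            return _BIN_OPS[type(node.op)](left, right)
        except ZeroDivisionError:
            return None
    return None


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render(ui: UIDocument, format: str = "html") -> str:
    """Serialize the interface model: canonical JSON or static HTML5.

    In HTML, every component is exactly one element carrying ``data-kind``
    and ``data-provenance`` attributes; labels ride along as ``aria-label``
    so the component/element correspondence stays one-to-one.
    """
    if format == "json":
        return ui.to_canonical_json()
    if format != "html":
        raise UsageError(f"unknown output format {format!r}")

    lines = [
        "<!DOCTYPE html>",
        '<html lang="en">',
        "<head>",
        '<meta charset="utf-8">',
        f"<title>{html.escape(str(ui.root_collection))}</title>",
        "</head>",
        "<body>",
        '<nav class="tab-bar"><ul>',
    ]

    def tab_list(tabs, depth=0):
        for tab in tabs:
            lines.append(f"<li>{html.escape(tab.label)}</li>")

    all_tabs: list[Tab] = []

    def collect(tab):
        all_tabs.append(tab)
        for sub in tab.sub_tabs:
            collect(sub)

    for tab in ui.tabs:
        collect(tab)
    tab_list(all_tabs)
    lines.append("</ul></nav>")

    for tab in all_tabs:
        lines.append(
            f'<section data-collection="{html.escape(str(tab.collection))}" '
            f'data-provenance="{html.escape(tab.provenance)}">'
        )
        lines.append(f"<h2>{html.escape(tab.label)}</h2>")
        for comp in tab.components:
            lines.append(_render_component(comp))
        lines.append("</section>")
    lines.append("</body>")
    lines.append("</html>")
    return "\n".join(lines) + "\n"


def _render_component(comp: UIComponent) -> str:
    attrs = {
        "data-kind": comp.kind,
        "data-provenance": comp.provenance,
        "aria-label": comp.label,
    }
    if comp.bound_rule is not None:
        attrs["data-rule"] = str(comp.bound_rule)
    value = comp.widget_config.get("value", "")
    active = comp.widget_config.get("active", True)

    def tag(name, extra=None, body=None, void=False):
        merged = dict(attrs)
        if extra:
            merged.update(extra)
        rendered = " ".join(
            f'{k}="{html.escape(str(v), quote=True)}"' for k, v in merged.items()
        )
        if void:
            return f"<{name} {rendered}>"
        return f"<{name} {rendered}>{body or ''}</{name}>"

    kind = comp.kind
    if kind == "date_field":
        extra = {"type": "date", "value": value}
        if not active:
            extra["readonly"] = "readonly"
        return tag("input", extra, void=True)
    if kind == "inactive_field":
        return tag("input", {"type": "text", "value": value,
                             "readonly": "readonly"}, void=True)
    if kind == "hidden_field":
        return tag("input", {"type": "hidden", "value": value}, void=True)
    if kind == "options_field":
        opts = comp.widget_config.get("options", [])
        body = "".join(
            f'<option{" selected" if o == value else ""}>{html.escape(o)}</option>'
            for o in opts
        )
        return tag("select", body=body)
    if kind == "formula_field":
        return tag("output",
                   {"data-formula": comp.widget_config.get("formula", "")},
                   body=html.escape(str(value)))
    if kind == "sub_tabs":
        return tag("nav", {"data-target": comp.widget_config.get(
            "target_collection", "")}, body=html.escape(comp.label))
    if kind == "link_field":
        return tag("a", {"href": "#" + comp.widget_config.get("target_rule", "")},
                   body=html.escape(comp.label))
    if kind == "label":
        return tag("span", body=html.escape(comp.label))
    # row / text_field and anything else: plain text input
    extra = {"type": "text", "value": value}
    if not active:
        extra["readonly"] = "readonly"
    return tag("input", extra, void=True)
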