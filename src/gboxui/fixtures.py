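"""Seeded synthetic clinical-trials projects.

The generator emulates a gastric-oncology data-capture schema: a root
"Patient ID" collection aggregates Demographics, Histology, Tissue and
Treatment collections through collection-valued rules; literal-valued rules
(name, gender, tumor grade, dates, doses...) hang off each collection.  Each
fictitious patient gets one item per collection, link statements attaching
the child items to the root item, and one literal statement per literal
rule, drawn reproducibly from editable value vocabularies under a seed.

Everything is deterministic: the same configuration and seed yield
byte-identical serialized projects.
"""

from __future__ import annotations

import importlib.resources
import random
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import ConfigurationError
from .gbox_schema import GBoxSpec, GuiRuleInstance, default_registry
from .s3db_store import KnowledgeBase, ResourceId, new_project

DEFAULT_COLLECTIONS = ("Patient ID", "Demographics", "Histology", "Tissue", "Treatment")


def default_vocabularies() -> dict:
    """The shipped schema + value vocabularies (editable YAML)."""
    text = (
        importlib.resources.files("gboxui.data")
        .joinpath("vocabularies.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


@dataclass
class FixtureConfig:
    n_patients: int = 50
    seed: int = 0
    collections: tuple[str, ...] = DEFAULT_COLLECTIONS
    vocabularies: Optional[dict] = None
    missingness: dict = field(default_factory=dict)  # rule verb -> rate in [0,1]
    access_key: str = "demo-key"

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if self.vocabularies is None:
            self.vocabularies = default_vocabularies()
        if self.collections[0] != self.vocabularies.get("root", "Patient ID"):
            raise ConfigurationError("the root collection must come first")


def _draw(rng: random.Random, spec: dict) -> str:
    kind = spec["type"]
    if kind in ("text", "options"):
        return rng.choice(spec["values"])
    if kind == "date":
        year = rng.randint(spec.get("start", 1930), spec.get("end", 1990))
        return f"{year:04d}-{rng.randint(1, 12):02d}-{rng.randint(1, 28):02d}"
    if kind == "number":
        return str(rng.randint(spec.get("low", 0), spec.get("high", 100)))
    raise ConfigurationError(f"unknown value type {kind!r}")


def generate_project(cfg: FixtureConfig) -> KnowledgeBase:
    """Build the synthetic project: TBox from the vocabularies, ABox per patient."""
    vocabs = cfg.vocabularies
    rng = random.Random(cfg.seed)
    kb = new_project(label="Synthetic gastric oncology trial",
                     access_key=cfg.access_key)

    root_label = cfg.collections[0]
    root = kb.add_collection(root_label)
    colls = {root_label: root}
    for name in cfg.collections[1:]:
        colls[name] = kb.add_collection(name)

    rule_specs: dict[str, dict] = {}
    for verb, spec in (vocabs.get("root_rules") or {}).items():
        kb.add_rule(root.id, verb, "date" if spec["type"] == "date"
                    else "number" if spec["type"] == "number" else "text")
        rule_specs[verb] = spec
    link_rules = {}
    for name in cfg.collections[1:]:
        link_rules[name] = kb.add_rule(root.id, name.lower(), colls[name].id)
    for name in cfg.collections[1:]:
        for verb, spec in (vocabs["collections"].get(name) or {}).items():
            tag = ("date" if spec["type"] == "date"
                   else "number" if spec["type"] == "number" else "text")
            kb.add_rule(colls[name].id, verb, tag)
            rule_specs[verb] = spec

    for i in range(cfg.n_patients):
        participant = f"{1001 + i}"
        patient = kb.add_item(root.id, participant)
        children = {}
        for name in cfg.collections[1:]:
            child = kb.add_item(colls[name].id, f"{participant}-{name}")
            kb.add_statement(patient.id, link_rules[name].id, child.id)
            children[name] = child
        for verb, spec in (vocabs.get("root_rules") or {}).items():
            rule = kb.rule_by_verb(verb)
            value = participant if verb == "participant number" else _draw(rng, spec)
            if rng.random() >= cfg.missingness.get(verb, 0.0):
                kb.add_statement(patient.id, rule.id, value)
        for name in cfg.collections[1:]:
            for verb, spec in (vocabs["collections"].get(name) or {}).items():
                rule = kb.rule_by_verb(verb)
                value = _draw(rng, spec)
                if rng.random() >= cfg.missingness.get(verb, 0.0):
                    kb.add_statement(children[name].id, rule.id, value)
    kb.validate()
    return kb


def generate_gbox(kb: KnowledgeBase, access_key: str = "demo-gui-key") -> GBoxSpec:
    """A companion GBox exercising each applicable named action.

    Date rules get hasDate, enumerations hasOptions (option lists derived
    from the observed statement values), free text hasText, the first link
    rule hasSubCollections, a storage field hasFieldInactive and the dose
    field hasFormula (a per-protocol derived dose from the cycle count).
    Rules with no observed values keep their defaults rather than receiving
    an empty options list.
    """
    registry = default_registry()
    instances: list[GuiRuleInstance] = []

    observed: dict[str, set] = {}
    for st in kb.statements.values():
        if not isinstance(st.value, ResourceId):
            observed.setdefault(str(st.rule), set()).add(st.value)

    links = kb.link_rules(kb.root_collection().id)
    if links:
        instances.append(GuiRuleInstance(domain=links[0].id,
                                         action="hasSubCollections"))
    for rule in sorted(kb.rules.values(), key=lambda r: r.id.serial):
        if rule.is_link:
            continue
        if rule.verb == "storage location":
            instances.append(GuiRuleInstance(domain=rule.id,
                                             action="hasFieldInactive"))
        elif rule.verb == "dose":
            instances.append(GuiRuleInstance(domain=rule.id, action="hasFormula",
                                             value="{cycles} * 25"))
        elif rule.object == "date":
            instances.append(GuiRuleInstance(domain=rule.id, action="hasDate"))
        elif rule.verb in ("gender", "tumor grade", "smoking status",
                           "tumor type", "sample type", "regimen"):
            vals = sorted(observed.get(str(rule.id), set()))
            if vals:
                instances.append(GuiRuleInstance(domain=rule.id,
                                                 action="hasOptions",
                                                 value="|".join(vals)))
        elif rule.verb == "name":
            instances.append(GuiRuleInstance(domain=rule.id, action="hasText"))

    spec = GBoxSpec(
        project=ResourceId("P", 2),
        actions=registry,
        rules=instances,
        label="Synthetic graphic rules",
        access_key=access_key,
    )
    spec.validate()
    return spec


def generate_import_table(cfg: FixtureConfig) -> tuple[str, str]:
    """A CSV and its YAML column→rule mapping, for tabular-import tests.

    The rows are drawn under ``cfg.seed`` offset from the project stream, so
    the table complements (rather than duplicates) the generated project.
    Import them into a schema-only project (``n_patients=0``).
    """
    vocabs = cfg.vocabularies
    rng = random.Random(cfg.seed + 7919)
    dem = vocabs["collections"]["Demographics"]
    his = vocabs["collections"]["Histology"]
    lines = ["participant number,name,gender,tumor grade"]
    for i in range(cfg.n_patients):
        lines.append(
            ",".join(
                [
                    f"{5001 + i}",
                    _draw(rng, dem["name"]),
                    _draw(rng, dem["gender"]),
                    _draw(rng, his["tumor grade"]),
                ]
            )
        )
    table = "\n".join(lines) + "\n"

    schema_kb = generate_project(
        FixtureConfig(n_patients=0, seed=cfg.seed, collections=cfg.collections,
                      vocabularies=vocabs, access_key=cfg.access_key)
    )
    mapping = {
        "key_column": "participant number",
        "root": str(schema_kb.root_collection().id),
        "columns": {
            "participant number": str(schema_kb.rule_by_verb("participant number").id),
            "name": str(schema_kb.rule_by_verb("name").id),
            "gender": str(schema_kb.rule_by_verb("gender").id),
            "tumor grade": str(schema_kb.rule_by_verb("tumor grade").id),
        },
    }
    return table, yaml.safe_dump(mapping, sort_keys=True)
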