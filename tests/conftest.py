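"""Shared fixtures: synthetic projects and an independent query oracle."""

import random

import pytest

from gboxui import fixtures
from gboxui.query_engine import Filter
from gboxui.s3db_store import KnowledgeBase, ResourceId


@pytest.fixture(scope="session")
def small_kb() -> KnowledgeBase:
    """Five synthetic patients under a fixed seed."""
    return fixtures.generate_project(fixtures.FixtureConfig(n_patients=5, seed=1))


@pytest.fixture(scope="session")
def small_gbox(small_kb):
    return fixtures.generate_gbox(small_kb)


@pytest.fixture(scope="session")
def schema_kb() -> KnowledgeBase:
    """Schema only: TBox rules, no patients."""
    return fixtures.generate_project(fixtures.FixtureConfig(n_patients=0, seed=1))


def brute_force_execute(plan, kb: KnowledgeBase) -> list[str]:
    """Independent oracle: exhaustive scan over every statement.

    For each parent item, each filter is checked by walking the raw
    statement list — directly for parent filters, through every link
    statement for child filters.  No indexes, no joins.
    """
    out = []
    statements = list(kb.statements.values())
    for item in kb.items_in(plan.parent):
        ok = True
        for f in plan.filters:
            if f.node == plan.parent:
                subjects = [item.id]
            else:
                subjects = []
                for st in statements:
                    if (
                        st.subject_item == item.id
                        and isinstance(st.value, ResourceId)
                        and kb.items[str(st.value)].collection == f.node
                    ):
                        subjects.append(st.value)
            hit = False
            for st in statements:
                if (
                    st.subject_item in subjects
                    and st.rule == f.rule
                    and not isinstance(st.value, ResourceId)
                    and f.matches(st.value)
                ):
                    hit = True
                    break
            if not hit:
                ok = False
                break
        if ok:
            out.append(item.identifier)
    return sorted(out)


def random_plan(kb: KnowledgeBase, rng: random.Random):
    """A random conjunctive selection over the fixture schema."""
    from gboxui.query_engine import build_plan

    root = kb.root_collection().id
    literal_rules = [
        r for r in kb.rules.values() if not r.is_link
    ]
    observed = {}
    for st in kb.statements.values():
        if not isinstance(st.value, ResourceId):
            observed.setdefault(str(st.rule), []).append(st.value)
    candidates = [r for r in literal_rules if observed.get(str(r.id))]
    n_filters = rng.randint(1, min(4, len(candidates)))
    filters = []
    for rule in rng.sample(candidates, n_filters):
        comparator = rng.choice(["equals", "contains"])
        if rng.random() < 0.8:
            literal = rng.choice(observed[str(rule.id)])
            if comparator == "contains" and len(literal) > 3 and rng.random() < 0.5:
                lo = rng.randrange(0, len(literal) - 2)
                literal = literal[lo : lo + 3]
        else:
            literal = rng.choice(["zzz", "female", "G2", "19", "a"])
        filters.append(
            Filter(node=rule.subject, rule=rule.id, comparator=comparator,
                   literal=literal)
        )
    return build_plan(filters, [], kb, parent=root)
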