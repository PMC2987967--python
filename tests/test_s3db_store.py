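"""Store model: round trips, imports, mutations, triple expansion."""

import pytest
from rdflib import Graph
from rdflib.compare import to_isomorphic

from gboxui import s3db_store as store
from gboxui.errors import (
    ConfigurationError,
    FormatError,
    IntegrityError,
    NotFoundError,
)
from gboxui.s3db_store import ResourceId, StatementSpec


def iso(doc_a: str, doc_b: str) -> bool:
    return to_isomorphic(Graph().parse(data=doc_a, format="turtle")) == to_isomorphic(
        Graph().parse(data=doc_b, format="turtle")
    )


class TestResourceId:
    def test_rendered_form_and_parse(self):
        rid = ResourceId("C", 1207734)
        assert str(rid) == "C1207734"
        assert ResourceId.parse("C1207734") == rid

    @pytest.mark.parametrize("bad", ["X1", "C", "12", "C-1", "c12"])
    def test_malformed_ids_rejected(self, bad):
        with pytest.raises(FormatError):
            ResourceId.parse(bad)

    def test_unknown_kind_rejected(self):
        with pytest.raises(IntegrityError):
            ResourceId("Q", 1)


class TestRoundTrip:
    @pytest.mark.parametrize("dialect", ["turtle", "n3"])
    def test_save_load_isomorphic(self, small_kb, dialect):
        doc = store.save_project(small_kb, dialect)
        kb2 = store.load_project(doc, dialect)
        assert iso(store.save_project(kb2, "turtle"), store.save_project(small_kb, "turtle"))
        assert kb2.warnings == []
        assert len(kb2.statements) == len(small_kb.statements)
        assert len(kb2.rules) == len(small_kb.rules)

    def test_empty_document_gives_empty_kb(self):
        kb = store.load_project("")
        assert kb.collections == {} and kb.warnings == []

    def test_empty_kb_serializes_to_project_node_only(self):
        doc = store.save_project(store.new_project())
        g = Graph().parse(data=doc, format="turtle")
        assert len(g) == 1  # just the project's type triple

    def test_statement_count_matches_element_tally(self, small_kb):
        doc = store.save_project(small_kb)
        g = Graph().parse(data=doc, format="turtle")
        # per element: project 1, collection 3, item 3, rule 4, statement 4 triples
        expected = (
            1
            + 3 * len(small_kb.collections)
            + 3 * len(small_kb.items)
            + 4 * len(small_kb.rules)
            + 4 * len(small_kb.statements)
        )
        # label and access key on the project node
        expected += bool(small_kb.label) + bool(small_kb.access_key)
        assert len(g) == expected

    def test_unknown_predicates_collected_not_dropped(self, small_kb):
        doc = store.save_project(small_kb)
        doc += '\n<https://gboxui.invalid/resource/P1/C2> <https://example.org/color> "red" .\n'
        kb = store.load_project(doc)
        assert any("color" in w for w in kb.warnings)
        assert len(kb.collections) == len(small_kb.collections)

    def test_parse_failure_raises_format_error(self):
        with pytest.raises(FormatError):
            store.load_project("@prefix broken")

    def test_integrity_violation_names_offender(self):
        kb = store.new_project()
        coll = kb.add_collection("Patients")
        item = kb.add_item(coll.id, "p1")
        rule = kb.add_rule(coll.id, "age", "number")
        kb.add_statement(item.id, rule.id, "41")
        doc = store.save_project(kb)
        ref = f"gb:subject <https://gboxui.invalid/resource/P1/{item.id}>"
        assert ref in doc
        broken = doc.replace(ref, ref.replace(f"/{item.id}>", "/I999>"))
        with pytest.raises(IntegrityError) as err:
            store.load_project(broken)
        assert "I999" in str(err.value)


class TestInvariants:
    def test_tbox_abox_partition(self, small_kb):
        assert set(small_kb.rules).isdisjoint(small_kb.statements)
        for st in small_kb.statements.values():
            assert str(st.rule) in small_kb.rules

    def test_statement_kind_must_match_rule(self):
        kb = store.new_project()
        a = kb.add_collection("A")
        b = kb.add_collection("B")
        item = kb.add_item(a.id, "x")
        other = kb.add_item(b.id, "y")
        literal_rule = kb.add_rule(a.id, "note", "text")
        link_rule = kb.add_rule(a.id, "partner", b.id)
        with pytest.raises(IntegrityError):
            kb.add_statement(item.id, literal_rule.id, other.id)
        with pytest.raises(IntegrityError):
            kb.add_statement(item.id, link_rule.id, "a string")

    def test_item_must_belong_to_rule_subject(self):
        kb = store.new_project()
        a = kb.add_collection("A")
        b = kb.add_collection("B")
        stray = kb.add_item(b.id, "y")
        rule = kb.add_rule(a.id, "note", "text")
        with pytest.raises(IntegrityError):
            kb.add_statement(stray.id, rule.id, "hello")

    def test_serials_are_monotone(self):
        kb = store.new_project()
        ids = [kb.add_collection(f"c{i}").id.serial for i in range(5)]
        assert ids == sorted(ids) and len(set(ids)) == 5


def _flat_kb():
    """Root collection with four literal rules, for exact import counts."""
    kb = store.new_project(access_key="k")
    root = kb.add_collection("Patient ID")
    for verb in ("participant number", "name", "gender", "grade"):
        kb.add_rule(root.id, verb, "text")
    return kb, root


class TestImportTabular:
    def _mapping(self, kb, root):
        return {
            "key_column": "participant number",
            "root": str(root.id),
            "columns": {
                verb: str(kb.rule_by_verb(verb).id)
                for verb in ("participant number", "name", "gender", "grade")
            },
        }

    def test_counts_match_non_empty_cells(self):
        kb, root = _flat_kb()
        table = (
            "participant number,name,gender,grade\n"
            "1,Ana,female,G2\n2,Rui,male,G1\n3,Eva,female,G3\n"
        )
        out = store.import_tabular(kb, table, self._mapping(kb, root))
        assert len(out.statements) == 12  # 3 rows x 4 mapped non-empty cells
        assert len(out.items) == 3

    def test_empty_cells_produce_no_statement(self):
        kb, root = _flat_kb()
        table = "participant number,name,gender,grade\n1,Ana,,G2\n2,,male,\n"
        out = store.import_tabular(kb, table, self._mapping(kb, root))
        assert len(out.statements) == 3 + 2  # count of non-empty mapped cells

    def test_idempotent_on_reimport(self):
        kb, root = _flat_kb()
        table = "participant number,name\n1,Ana\n"
        mapping = self._mapping(kb, root)
        once = store.import_tabular(kb, table, mapping)
        twice = store.import_tabular(once, table, mapping)
        assert len(twice.statements) == len(once.statements)
        assert len(twice.items) == len(once.items)

    def test_empty_table_is_identity(self):
        kb, root = _flat_kb()
        out = store.import_tabular(kb, "", self._mapping(kb, root))
        assert out.statements == {} and out.items == {}

    def test_missing_key_column_is_configuration_error(self):
        kb, root = _flat_kb()
        mapping = self._mapping(kb, root)
        del mapping["key_column"]
        with pytest.raises(ConfigurationError):
            store.import_tabular(kb, "name\nAna\n", mapping)
        mapping["key_column"] = "participant number"
        with pytest.raises(ConfigurationError):
            store.import_tabular(kb, "name\nAna\n", mapping)

    def test_child_collection_columns_create_linked_items(self, schema_kb):
        from gboxui.fixtures import FixtureConfig, generate_import_table

        table, mapping = generate_import_table(FixtureConfig(n_patients=3, seed=1))
        out = store.import_tabular(schema_kb, table, mapping)
        root = out.root_collection()
        patients = out.items_in(root.id)
        assert len(patients) == 3
        # each patient carries its literal root statement plus links to the
        # child items holding the demographics/histology values
        grade_rule = out.rule_by_verb("tumor grade")
        grades = [
            st.value
            for st in out.statements.values()
            if st.rule == grade_rule.id
        ]
        assert len(grades) == 3


class TestMutate:
    def test_insert_then_delete_is_identity(self, small_kb):
        rule = small_kb.rule_by_verb("name")
        item = small_kb.items_in(rule.subject)[0]
        spec = StatementSpec(item=item.id, rule=rule.id, value="Temp Name")
        inserted = store.mutate(small_kb, "insert", spec)
        assert len(inserted.statements) == len(small_kb.statements) + 1
        new_id = (set(inserted.statements) - set(small_kb.statements)).pop()
        back = store.mutate(
            inserted, "delete", StatementSpec(item.id, rule.id,
                                              statement=ResourceId.parse(new_id))
        )
        assert {k: (str(v.subject_item), str(v.rule), str(v.value))
                for k, v in back.statements.items()} == {
            k: (str(v.subject_item), str(v.rule), str(v.value))
            for k, v in small_kb.statements.items()
        }

    def test_update_changes_only_target_value(self, small_kb):
        rule = small_kb.rule_by_verb("date of birth")
        item = small_kb.items_in(rule.subject)[0]
        target = small_kb.statements_of(item.id, rule.id)[0]
        updated = store.mutate(
            small_kb, "update", StatementSpec(item.id, rule.id, value="1970-01-01")
        )
        diffs = [
            sid
            for sid in small_kb.statements
            if str(small_kb.statements[sid].value) != str(updated.statements[sid].value)
        ]
        assert diffs == [str(target.id)]
        assert updated.statements[str(target.id)].value == "1970-01-01"

    def test_patient_scoped_mutation_touches_one_item_only(self, small_kb):
        rule = small_kb.rule_by_verb("gender")
        items = small_kb.items_in(rule.subject)
        first = items[0]
        updated = store.mutate(
            small_kb, "update", StatementSpec(first.id, rule.id, value="female")
        )
        for sid, st in updated.statements.items():
            if str(st.value) != str(small_kb.statements[sid].value):
                assert st.subject_item == first.id

    def test_missing_target_raises_not_found(self, small_kb):
        with pytest.raises(NotFoundError):
            store.mutate(
                small_kb,
                "delete",
                StatementSpec(ResourceId("I", 99999), ResourceId("R", 7)),
            )

    def test_kind_mismatch_raises_integrity(self, small_kb):
        rule = small_kb.rule_by_verb("gender")
        item = small_kb.items_in(rule.subject)[0]
        other_item = small_kb.items_in(rule.subject)[1]
        with pytest.raises(IntegrityError):
            store.mutate(
                small_kb, "update",
                StatementSpec(item.id, rule.id, value=other_item.id),
            )


class TestExpandTriples:
    def test_single_rule_no_statements(self):
        kb = store.new_project()
        coll = kb.add_collection("A")
        kb.add_rule(coll.id, "note", "text")
        g = store.expand_triples(kb)
        assert len(g) == 1

    def test_count_is_rules_plus_statements(self, small_kb):
        g = store.expand_triples(small_kb)
        assert len(g) == len(small_kb.rules) + len(small_kb.statements)

    def test_serialization_is_deterministic(self, small_kb):
        a = store.triples_as_text(store.expand_triples(small_kb))
        b = store.triples_as_text(store.expand_triples(small_kb))
        assert a == b
        assert a == "".join(sorted(a.splitlines(keepends=True)))
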