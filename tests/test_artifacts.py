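"""Conformance-artifact parsing: profiles, logical model, code systems,
value sets, path resolution."""

import pytest

from feasquery.artifacts import (
    CodeSystemModel,
    TermCode,
    element_by_path,
    parse_code_system,
    parse_logical_model,
    parse_structure_definition,
    parse_value_set,
)
from feasquery.errors import (
    ArtifactParseError,
    CyclicHierarchyError,
    ElementNotFoundError,
    UnsupportedDocumentError,
)


def _condition_sd(n_extra=0):
    elements = [
        {"path": "Condition"},
        {
            "path": "Condition.code",
            "type": [{"code": "CodeableConcept"}],
            "binding": {"strength": "required",
                        "valueSet": "http://ex.org/vs/cld"},
        },
    ]
    for i in range(n_extra):
        elements.append({"path": f"Condition.extra{i:02d}"})
    return {
        "resourceType": "StructureDefinition",
        "url": "http://ex.org/sd/cld",
        "name": "ChronicLungDisease",
        "type": "Condition",
        "snapshot": {"element": elements},
    }


class TestStructureDefinition:
    def test_minimal_condition_profile_reads_through(self):
        profile = parse_structure_definition(_condition_sd())
        assert profile.resource_type == "Condition"
        bound = [e for e in profile.elements if e.binding_url]
        assert len(bound) == 1
        assert bound[0].path == "Condition.code"
        assert bound[0].binding_url == "http://ex.org/vs/cld"

    def test_missing_resource_type_is_unsupported(self):
        with pytest.raises(UnsupportedDocumentError):
            parse_structure_definition({"name": "X"})

    def test_element_count_and_order_preserved(self):
        doc = _condition_sd(n_extra=8)  # 10 elements in total
        profile = parse_structure_definition(doc)
        assert len(profile.elements) == len(doc["snapshot"]["element"]) == 10
        assert [e.path for e in profile.elements] == [
            el["path"] for el in doc["snapshot"]["element"]
        ]

    def test_choice_type_path_normalized_to_constrained_type(self):
        doc = _condition_sd()
        doc["snapshot"]["element"].append({
            "path": "Condition.onset[x]", "type": [{"code": "Age"}],
        })
        profile = parse_structure_definition(doc)
        assert any(e.path == "Condition.onsetAge" for e in profile.elements)

    def test_differential_only_accepted(self):
        doc = _condition_sd()
        doc["differential"] = doc.pop("snapshot")
        assert parse_structure_definition(doc).resource_type == "Condition"

    def test_reserialize_reparse_roundtrip(self, artifacts):
        for profile in artifacts.profiles.values():
            again = parse_structure_definition(profile.to_structure_definition())
            assert again.resource_type == profile.resource_type
            assert [e.path for e in again.elements] == [
                e.path for e in profile.elements
            ]
            assert [e.binding_url for e in again.elements] == [
                e.binding_url for e in profile.elements
            ]


def _logical_model(categories):
    elements = [{"path": "Model"}]
    for cat, crits in categories.items():
        elements.append({"path": f"Model.{cat}"})
        elements.extend({"path": f"Model.{cat}.{c}"} for c in crits)
    return {
        "resourceType": "StructureDefinition",
        "kind": "logical",
        "type": "Model",
        "differential": {"element": elements},
    }


class TestLogicalModel:
    def test_categories_and_criteria_in_document_order(self):
        cats = parse_logical_model(_logical_model(
            {"Demographics": ["Age"], "Symptoms": ["Cough", "Fever"]}
        ))
        assert [c.name for c in cats] == ["Demographics", "Symptoms"]
        assert [c.criterion_names for c in cats] == [
            ["Age"], ["Cough", "Fever"]
        ]

    def test_empty_model_yields_no_categories(self):
        assert parse_logical_model(_logical_model({})) == []

    def test_duplicate_criterion_in_category_rejected(self):
        with pytest.raises(ArtifactParseError, match="duplicate criterion"):
            parse_logical_model(_logical_model({"A": ["X", "X"]}))

    def test_shallow_model_warns_and_keeps_empty_criteria(self):
        doc = _logical_model({"OnlyCategory": []})
        with pytest.warns(UserWarning, match="no second-level"):
            cats = parse_logical_model(doc)
        assert [c.criterion_names for c in cats] == [[]]

    def test_gecco_shaped_model_counts(self):
        shape = {f"Cat{i:02d}": [f"Crit{i:02d}_{j:02d}" for j in range(
            7 if i < 5 else 6)] for i in range(13)}
        cats = parse_logical_model(_logical_model(shape))
        total = sum(len(c.criterion_names) for c in cats)
        assert len(cats) == 13
        assert total == sum(len(v) for v in shape.values()) == 83


def _nested_cs():
    return {
        "resourceType": "CodeSystem",
        "url": "http://ex.org/cs/toy",
        "concept": [{
            "code": "R", "display": "Root",
            "concept": [
                {"code": "A", "display": "A", "concept": [
                    {"code": "A1", "display": "A1"},
                    {"code": "A2", "display": "A2"},
                ]},
                {"code": "B", "display": "B", "concept": [
                    {"code": "B1", "display": "B1"},
                    {"code": "B2", "display": "B2"},
                ]},
            ],
        }],
    }


class TestCodeSystem:
    def test_nested_three_level_counts(self):
        cs = parse_code_system(_nested_cs())
        assert len(cs.concepts) == 7
        assert len(cs.parent_edges) == 6

    def test_parent_property_encoding_is_equivalent(self):
        nested = parse_code_system(_nested_cs())
        flat = {
            "resourceType": "CodeSystem",
            "url": "http://ex.org/cs/toy",
            "concept": [
                {"code": c, "display": d, **({"property": [
                    {"code": "parent", "valueCode": p}
                ]} if p else {})}
                for c, d, p in [
                    ("R", "Root", None), ("A", "A", "R"), ("A1", "A1", "A"),
                    ("A2", "A2", "A"), ("B", "B", "R"), ("B1", "B1", "B"),
                    ("B2", "B2", "B"),
                ]
            ],
        }
        parsed = parse_code_system(flat)
        assert parsed.concepts == nested.concepts
        assert sorted(parsed.parent_edges) == sorted(nested.parent_edges)

    def test_self_edge_is_a_cycle(self):
        with pytest.raises(CyclicHierarchyError):
            CodeSystemModel(
                url="http://ex.org/cs", concepts={"A": "A"},
                parent_edges=[("A", "A")],
            )

    def test_longer_cycle_reported_with_members(self):
        with pytest.raises(CyclicHierarchyError) as exc:
            CodeSystemModel(
                url="http://ex.org/cs",
                concepts={"A": "A", "B": "B"},
                parent_edges=[("A", "B"), ("B", "A")],
            )
        assert set(exc.value.cycle) == {"A", "B"}


class TestValueSet:
    def _doc(self, includes):
        return {
            "resourceType": "ValueSet",
            "url": "http://ex.org/vs/x",
            "compose": {"include": includes},
        }

    def test_whole_system_rule(self):
        vs = parse_value_set(self._doc([{"system": "http://ex.org/cs/s"}]))
        (rule,) = vs.include_rules
        assert rule.codes is None and rule.filter_anchor is None

    def test_is_a_filter_anchor(self):
        vs = parse_value_set(self._doc([{
            "system": "http://ex.org/cs/s",
            "filter": [{"property": "concept", "op": "is-a", "value": "A"}],
        }]))
        assert vs.include_rules[0].filter_anchor == "A"

    def test_two_includes_preserve_system_order(self):
        vs = parse_value_set(self._doc([
            {"system": "http://ex.org/cs/one", "concept": [{"code": "x"}]},
            {"system": "http://ex.org/cs/two", "concept": [{"code": "y"}]},
        ]))
        assert [r.system for r in vs.include_rules] == [
            "http://ex.org/cs/one", "http://ex.org/cs/two"
        ]

    def test_missing_compose_warns_and_yields_no_rules(self):
        with pytest.warns(UserWarning, match="no compose"):
            vs = parse_value_set({
                "resourceType": "ValueSet", "url": "http://ex.org/vs/x",
            })
        assert vs.include_rules == []


class TestElementByPath:
    def test_exact_and_missing_paths(self):
        profile = parse_structure_definition(_condition_sd())
        assert element_by_path(profile, "Condition.code").binding_url
        with pytest.raises(ElementNotFoundError):
            element_by_path(profile, "Condition.bodySite")

    def test_choice_path_resolves_constrained_type(self, artifacts):
        weight = artifacts.profiles["BodyWeight"]
        el = element_by_path(weight, "Observation.value[x]")
        assert el.path == "Observation.valueQuantity"


class TestTermCode:
    def test_identity_ignores_display_and_version(self):
        a = TermCode("http://ex.org/cs", "X", "Label", "1.0")
        b = TermCode("http://ex.org/cs", "X", "Other label", "2.0")
        assert a == b and hash(a) == hash(b)

    def test_empty_system_or_code_rejected(self):
        with pytest.raises(ValueError):
            TermCode("", "X")
        with pytest.raises(ValueError):
            TermCode("http://ex.org/cs", "")
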