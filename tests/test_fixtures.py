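"""Synthetic study generation and the brute-force evaluators."""

import math
import random

import pytest

from feasquery.artifacts import TermCode
from feasquery.errors import EvaluationError
from feasquery.fixtures import (
    FAULT_CLASSES,
    FixtureSpec,
    ResourceStore,
    StoredResource,
    build_criterion_test_suite,
    eval_filter,
    eval_sq_bruteforce,
    gen_artifacts,
    gen_patients,
    inject_faults,
    run_suite,
)
from feasquery.pipeline import run_generation
from feasquery.sq import CriterionClause, StructuredQuery, WireTermCode
from feasquery.systems import ICD10GM
from feasquery.translate import QuantityConstraint, SearchFilter


def _single_criterion_sq(system, code):
    return StructuredQuery(inclusion=[[CriterionClause(
        term_codes=[WireTermCode(system=system, code=code)]
    )]])


class TestArtifactGeneration:
    def test_same_seed_is_reproducible(self, tmp_path):
        from feasquery.fixtures import write_artifact_directory

        spec = FixtureSpec(seed=3)
        for sub in ("a", "b"):
            write_artifact_directory(gen_artifacts(spec), tmp_path / sub)
        files_a = sorted((tmp_path / "a").rglob("*.json"))
        files_b = sorted((tmp_path / "b").rglob("*.json"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes()

    def test_roster_covers_every_resource_type_and_corner_case(
            self, artifacts):
        types = {p.resource_type for p in artifacts.profiles.values()}
        assert {"Condition", "Observation", "Procedure",
                "MedicationStatement", "Immunization", "DiagnosticReport",
                "Specimen", "Patient"} <= types
        from feasquery.ontology import default_corner_case_registry

        assert set(default_corner_case_registry()) <= set(artifacts.profiles)

    def test_mixed_system_value_set_present(self, artifacts):
        mixed = [
            vs for vs in artifacts.value_sets.values()
            if len({r.system for r in vs.include_rules}) > 1
        ]
        assert mixed, "a ValueSet must span two systems to exercise the "\
            "single-CodeSystem preference rule"

    def test_degenerate_spec_single_concept_ontology(self):
        spec = FixtureSpec(
            seed=0, n_systems=1, codes_per_system=1, n_categories=1,
            profiles_per_category=1, include_roster=False,
        )
        generated = run_generation(gen_artifacts(spec))
        assert len(generated.mapping) == 1

    def test_invalid_shape_rejected(self):
        with pytest.raises(ValueError):
            FixtureSpec(n_patients=0)
        with pytest.raises(ValueError):
            FixtureSpec(criterion_prevalence=1.5)

    def test_directory_roundtrip_reproduces_generation(
            self, tmp_path, artifacts):
        from feasquery.artifacts import load_artifact_directory
        from feasquery.fixtures import write_artifact_directory
        import json

        write_artifact_directory(artifacts, tmp_path)
        loaded = load_artifact_directory(tmp_path)
        a = run_generation(artifacts)
        b = run_generation(loaded)
        assert json.dumps(a.mapping.to_json()) == json.dumps(
            b.mapping.to_json()
        )


class TestPatientGeneration:
    def test_zero_prevalence_no_criterion_resources(self, artifacts):
        spec = FixtureSpec(seed=5, n_patients=10, criterion_prevalence=0.0,
                           unconfirmed_rate=0.0)
        store = gen_patients(spec, artifacts)
        assert store.resources == []

    def test_full_prevalence_every_patient_matches_every_leaf(
            self, artifacts):
        spec = FixtureSpec(seed=5, n_patients=8, criterion_prevalence=1.0)
        generated = run_generation(artifacts)
        store = gen_patients(spec, artifacts, generated)
        cases = build_criterion_test_suite(generated, store)
        for case in cases:
            assert case.expected_patient_ids == frozenset(store.patients)

    def test_empirical_frequency_within_three_standard_errors(
            self, artifacts):
        prevalence = 0.3
        n = 2000
        spec = FixtureSpec(seed=6, n_patients=n,
                           criterion_prevalence=prevalence,
                           unconfirmed_rate=0.0)
        generated = run_generation(artifacts)
        store = gen_patients(spec, artifacts, generated)
        counts = {}
        for entry in generated.mapping:
            holders = {
                r.patient for r in store.resources
                if r.coded.get(entry.term_code_fhir_path) == entry.key
            }
            counts[entry.key.key] = len(holders)
        se = math.sqrt(prevalence * (1 - prevalence) / n)
        for key, count in counts.items():
            assert abs(count / n - prevalence) < 3 * se, key


class TestEvalFilter:
    def _tiny_store(self):
        cs = "http://ex.org/cs"
        store = ResourceStore(
            patients=[f"P{i}" for i in range(5)],
            param_paths={
                ("Condition", "code"): "Condition.code",
                ("Observation", "code"): "Observation.code",
                ("Observation", "value-quantity"): "Observation.valueQuantity",
            },
        )
        data = [
            ("Condition", "P0", {"Condition.code": TermCode(cs, "A")}, {}),
            ("Condition", "P1", {"Condition.code": TermCode(cs, "B")}, {}),
            ("Observation", "P1", {"Observation.code": TermCode(cs, "W")},
             {"Observation.valueQuantity": (70.0, "kg")}),
            ("Observation", "P2", {"Observation.code": TermCode(cs, "W")},
             {"Observation.valueQuantity": (71.5, "kg")}),
            ("Observation", "P3", {"Observation.code": TermCode(cs, "W")},
             {"Observation.valueQuantity": (80.0, "g")}),
            ("Condition", "P3", {"Condition.code": TermCode(cs, "A")}, {}),
            ("Condition", "P4", {"Condition.code": TermCode(cs, "C")}, {}),
            ("Observation", "P4", {"Observation.code": TermCode(cs, "X")},
             {"Observation.valueQuantity": (90.0, "kg")}),
        ]
        for rt, pid, coded, quantities in data:
            store.resources.append(StoredResource(
                resource_type=rt, patient=pid, coded=coded,
                quantities=quantities,
            ))
        return store, cs

    def test_matches_hand_enumeration(self):
        store, cs = self._tiny_store()
        f = SearchFilter(
            resource_type="Condition", term_param="code",
            token_params=(("code", (TermCode(cs, "A"), TermCode(cs, "C"))),),
        )
        assert eval_filter(store, f) == {"P0", "P3", "P4"}

    def test_strict_comparator_boundary(self):
        store, cs = self._tiny_store()
        f = SearchFilter(
            resource_type="Observation", term_param="code",
            token_params=(("code", (TermCode(cs, "W"),)),),
            quantity_params=(
                ("value-quantity", (QuantityConstraint("gt", 70.0, "kg"),)),
            ),
        )
        # P1 holds exactly 70 kg: gt excludes it; P3's unit differs
        assert eval_filter(store, f) == {"P2"}

    def test_unknown_parameter_is_an_evaluation_error(self):
        store, cs = self._tiny_store()
        f = SearchFilter(
            resource_type="Condition", term_param="oops",
            token_params=(("oops", (TermCode(cs, "A"),)),),
        )
        with pytest.raises(EvaluationError):
            eval_filter(store, f)


class TestBruteForce:
    def test_single_criterion_matches_translated_filter(
            self, generated, store):
        from feasquery.translate import criterion_to_search_filter

        sq = _single_criterion_sq(ICD10GM, "J44")
        want = eval_sq_bruteforce(
            store, sq, generated.term_tree, generated.mapping
        )
        f = criterion_to_search_filter(
            sq.inclusion[0][0], generated.mapping, generated.term_tree
        )
        assert eval_filter(store, f) == want

    def test_self_cancellation_yields_empty_cohort(self, generated, store):
        clause = [CriterionClause(
            term_codes=[WireTermCode(system=ICD10GM, code="J44")]
        )]
        sq = StructuredQuery(inclusion=[clause], exclusion=[clause])
        assert eval_sq_bruteforce(
            store, sq, generated.term_tree, generated.mapping
        ) == set()

    def test_de_morgan_on_exclusion(self, generated, store):
        d = CriterionClause(
            term_codes=[WireTermCode(system=ICD10GM, code="J44.0")]
        )
        e = CriterionClause(
            term_codes=[WireTermCode(system=ICD10GM, code="J45.0")]
        )

        def crit(c):
            sq = StructuredQuery(inclusion=[[c]])
            return eval_sq_bruteforce(
                store, sq, generated.term_tree, generated.mapping
            )

        both = crit(d) & crit(e)
        everyone = set(store.patients)
        sq = StructuredQuery(
            inclusion=[[CriterionClause(term_codes=[
                WireTermCode(system=ICD10GM, code="J40-J47"),
                WireTermCode(system=ICD10GM, code="G47.3"),
            ])]],
            exclusion=[[d, e]],
        )
        inclusion_only = StructuredQuery(inclusion=sq.inclusion)
        inc = eval_sq_bruteforce(
            store, inclusion_only, generated.term_tree, generated.mapping
        )
        got = eval_sq_bruteforce(
            store, sq, generated.term_tree, generated.mapping
        )
        assert got == inc & (everyone - both)


class TestCriterionSuite:
    def test_suite_size_equals_selectable_leaves(self, generated, store):
        from feasquery.fixtures import _leaf_keys

        cases = build_criterion_test_suite(generated, store)
        assert len(cases) == len(_leaf_keys(generated))

    def test_consistent_fixture_passes_everywhere(self, generated, store):
        cases = build_criterion_test_suite(generated, store)
        report = run_suite(cases, store, generated, seed=11)
        assert report.ok and report.n_passed == report.n_cases

    def test_fault_injection_produces_classified_failures(
            self, generated, store):
        mutated, fault_map = inject_faults(
            store, generated, random.Random(21)
        )
        assert set(fault_map.values()) == set(FAULT_CLASSES)
        cases = build_criterion_test_suite(generated, store)
        report = run_suite(cases, mutated, generated, fault_map)
        assert len(report.failures) == len(fault_map)
        assert {cls for _, cls in report.failures} == set(FAULT_CLASSES)
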