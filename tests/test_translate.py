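"""SQ translation: widening, filter construction, plan shape, FHIR Search
rendering, CQL consistency."""

import random

import pytest

from feasquery.artifacts import TermCode
from feasquery.errors import (
    HeterogeneousExpansionError,
    TranslationError,
    UnmappedCriterionError,
)
from feasquery.fixtures import generate_random_sq
from feasquery.mapping import TermTreeNode
from feasquery.sq import (
    CriterionClause,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    StructuredQuery,
    WireTermCode,
)
from feasquery.systems import ICD10GM, LOINC, UCUM
from feasquery.translate import (
    PlanLeaf,
    PlanOp,
    QuantityConstraint,
    SearchFilter,
    criterion_to_search_filter,
    criterion_to_search_filters,
    expand_criterion,
    render_fhir_search,
    sq_to_cql,
    sq_to_cql_library,
    sq_to_query_plan,
)


def _clause(*codes, vf=None, system=ICD10GM):
    return CriterionClause(
        term_codes=[WireTermCode(system=system, code=c) for c in codes],
        value_filter=vf,
    )


def _sq(inclusion, exclusion=()):
    return StructuredQuery(inclusion=inclusion, exclusion=list(exclusion))


class TestExpandCriterion:
    def test_non_leaf_widens_to_descendants(self, generated):
        got = expand_criterion(_clause("J44"), generated.term_tree)
        assert {tc.code for tc in got} == {"J44", "J44.0", "J44.1"}

    def test_leaf_stays_singleton(self, generated):
        got = expand_criterion(_clause("J44.0"), generated.term_tree)
        assert [tc.code for tc in got] == ["J44.0"]

    def test_absent_code_passes_through_with_warning(self, generated):
        with pytest.warns(UserWarning, match="not in the terminology tree"):
            got = expand_criterion(_clause("X99"), generated.term_tree)
        assert [tc.code for tc in got] == ["X99"]


class TestCriterionFilters:
    def test_condition_filter_tokens_and_fixed_criterion(self, generated):
        f = criterion_to_search_filter(
            _clause("J44"), generated.mapping, generated.term_tree
        )
        assert f.resource_type == "Condition"
        ((param, tokens),) = f.token_params
        assert param == "code"
        assert {tc.code for tc in tokens} == {"J44", "J44.0", "J44.1"}
        ((fixed_param, fixed_tokens),) = f.fixed_params
        assert fixed_param == "verification-status"
        assert fixed_tokens[0].code == "confirmed"

    def test_quantity_comparator_constraint(self, generated):
        vf = QuantityComparatorFilter(comparator="gt", value=70, unit="kg")
        f = criterion_to_search_filter(
            _clause("29463-7", system=LOINC, vf=vf),
            generated.mapping, generated.term_tree,
        )
        ((param, constraints),) = f.quantity_params
        assert param == "value-quantity"
        assert constraints[0].render() == f"gt70|{UCUM}|kg"

    def test_quantity_range_renders_two_constraints(self, generated):
        vf = QuantityRangeFilter(min_value=60, max_value=80, unit="kg")
        f = criterion_to_search_filter(
            _clause("29463-7", system=LOINC, vf=vf),
            generated.mapping, generated.term_tree,
        )
        ((_, constraints),) = f.quantity_params
        assert [c.render() for c in constraints] == [
            f"ge60|{UCUM}|kg", f"le80|{UCUM}|kg",
        ]

    def test_value_filter_on_codeless_criterion_rejected(self, generated):
        vf = QuantityComparatorFilter(comparator="gt", value=1, unit="kg")
        with pytest.raises(TranslationError, match="does not accept"):
            criterion_to_search_filter(
                _clause("J44.0", vf=vf), generated.mapping, generated.term_tree
            )

    def test_heterogeneous_codes_split_or_error(self, generated):
        clause = CriterionClause(term_codes=[
            WireTermCode(system=ICD10GM, code="J44.0"),
            WireTermCode(system=LOINC, code="29463-7"),
        ])
        filters = criterion_to_search_filters(
            clause, generated.mapping, generated.term_tree
        )
        assert {f.resource_type for f in filters} == {
            "Condition", "Observation"
        }
        with pytest.raises(HeterogeneousExpansionError):
            criterion_to_search_filter(
                clause, generated.mapping, generated.term_tree
            )

    def test_unmapped_code_errors(self, generated):
        clause = _clause("J44")
        bad_tree = [TermTreeNode(term_code=TermCode(ICD10GM, "J44"))]
        # J44 resolves but with an empty mapping it cannot translate
        from feasquery.mapping import CriterionMapping

        with pytest.raises(UnmappedCriterionError):
            criterion_to_search_filter(clause, CriterionMapping(), bad_tree)


class TestPlanShape:
    def test_formula_shape_with_exclusion(self, generated):
        sq = _sq(
            inclusion=[[_clause("J44.0"), _clause("J45.0")], [_clause("J47")]],
            exclusion=[[_clause("G47.3"), _clause("J44.1")]],
        )
        plan = sq_to_query_plan(sq, generated.mapping, generated.term_tree)
        root = plan.root
        assert isinstance(root, PlanOp) and root.op == "DIFFERENCE"
        inc, exc = root.children
        assert inc.op == "INTERSECT"
        assert all(child.op == "UNION" for child in inc.children)
        assert exc.op == "UNION"
        assert all(child.op == "INTERSECT" for child in exc.children)

    def test_no_difference_node_without_exclusion(self, generated):
        plan = sq_to_query_plan(
            _sq([[_clause("J44.0")]]), generated.mapping, generated.term_tree
        )
        ops = []

        def walk(node):
            if isinstance(node, PlanOp):
                ops.append(node.op)
                for c in node.children:
                    walk(c)

        walk(plan.root)
        assert "DIFFERENCE" not in ops

    def test_invalid_sq_refused(self, generated):
        with pytest.raises(TranslationError):
            sq_to_query_plan(
                StructuredQuery(inclusion=[]),
                generated.mapping, generated.term_tree,
            )


class TestRendering:
    def test_empty_filter_renders_bare_resource_query(self):
        f = SearchFilter(resource_type="Condition", term_param="code")
        assert render_fhir_search(f) == "Condition?"

    def test_percent_encoding_of_system_and_pipe(self):
        f = SearchFilter(
            resource_type="Condition", term_param="code",
            token_params=(
                ("code", (TermCode("http://ex.org/cs", "A1"),)),
            ),
        )
        assert render_fhir_search(f) == (
            "Condition?code=http%3A%2F%2Fex.org%2Fcs%7CA1"
        )

    def test_tokens_comma_joined_and_sorted(self, generated):
        f = criterion_to_search_filter(
            _clause("J44"), generated.mapping, generated.term_tree
        )
        request = render_fhir_search(f)
        assert request.startswith("Condition?code=")
        code_part = request.split("&")[0]
        assert code_part.count("%2C") == 0 and code_part.count(",") == 2

    def test_rendering_is_deterministic(self, generated):
        f = criterion_to_search_filter(
            _clause("J40-J47"), generated.mapping, generated.term_tree
        )
        assert render_fhir_search(f) == render_fhir_search(f)


class TestCql:
    def test_inclusion_only_has_no_negation(self, generated):
        text = sq_to_cql(
            _sq([[_clause("J44.0")]]), generated.mapping, generated.term_tree
        )
        population = text.split('define "InInitialPopulation":')[1]
        assert " not " not in population

    def test_exclusion_renders_and_not(self, generated):
        text = sq_to_cql(
            _sq([[_clause("J44.0")]], exclusion=[[_clause("J45.0")]]),
            generated.mapping, generated.term_tree,
        )
        population = text.split('define "InInitialPopulation":')[1]
        assert "and not (" in population

    def test_code_lists_match_fhir_search_tokens(self, generated):
        rng = random.Random(5)
        for _ in range(50):
            sq = generate_random_sq(rng, generated)
            lib = sq_to_cql_library(sq, generated.mapping, generated.term_tree)
            plan = sq_to_query_plan(sq, generated.mapping, generated.term_tree)
            cql_sets = sorted(
                tuple(sorted(tc.key for tc in d.code_set))
                for d in lib.defines
            )
            search_sets = sorted(
                tuple(sorted(tc.key for tc in f.term_tokens))
                for f in plan.leaves()
            )
            assert cql_sets == search_sets
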