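"""Translating Structured Queries into FHIR Search plans and CQL.

FHIR Search cannot express a whole inclusion/exclusion query in one request,
so an SQ is translated into a *query plan*: a set-algebra expression whose
leaves are single FHIR Search filters (each evaluable to a patient-ID set)
and whose operators are UNION, INTERSECT and DIFFERENCE.  The plan's shape
mirrors the SQ formula exactly::

    (INTERSECT over inclusion clauses of UNION over their criteria)
    DIFFERENCE
    (UNION over exclusion clauses of INTERSECT over their criteria)

with the DIFFERENCE present exactly once, at the root, iff the exclusion is
non-empty.

Criterion codes are widened to their descendants through the terminology
tree by the translator itself — the sites run no terminology server, so the
server-side ``:below`` modifier is not available.  Within one criterion, OR
over codes renders as comma-joined tokens of a single search parameter; if
the widened codes span different resource types or parameters, the criterion
becomes a UNION over one filter per compatible group.

The CQL emitter produces a self-contained library (inline code lists, no
ValueSet references) with one define per criterion and a population define
combining them with and/or/not per the SQ formula.  Each define's code list
equals the token set of the corresponding FHIR Search filter.
"""

from __future__ import annotations

import urllib.parse
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

from .artifacts import TermCode
from .errors import HeterogeneousExpansionError, TranslationError
from .mapping import CriterionMapping, MappingEntry, TermTreeNode, tree_descendants
from .sq import (
    ConceptFilter,
    CriterionClause,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    StructuredQuery,
)
from .systems import UCUM

__all__ = [
    "QuantityConstraint",
    "SearchFilter",
    "PlanLeaf",
    "PlanOp",
    "QueryPlan",
    "expand_criterion",
    "criterion_to_search_filter",
    "criterion_to_search_filters",
    "sq_to_query_plan",
    "render_fhir_search",
    "render_plan_requests",
    "CqlDefine",
    "CqlLibrary",
    "sq_to_cql_library",
    "sq_to_cql",
]

CONCEPT_KINDS = ("concept", "component-concept", "conclusion-text")
QUANTITY_KINDS = ("quantity", "component-quantity", "integer-score")


@dataclass(frozen=True)
class QuantityConstraint:
    comparator: str  # eq|ne|le|ge|lt|gt
    value: float
    unit: str

    def render(self) -> str:
        prefix = "" if self.comparator == "eq" else self.comparator
        return f"{prefix}{self.value:g}|{UCUM}|{self.unit}"


@dataclass(frozen=True)
class SearchFilter:
    """One FHIR Search request, evaluable to a set of patient IDs."""

    resource_type: str
    term_param: str
    token_params: tuple[tuple[str, tuple[TermCode, ...]], ...] = ()
    quantity_params: tuple[tuple[str, tuple[QuantityConstraint, ...]], ...] = ()
    fixed_params: tuple[tuple[str, tuple[TermCode, ...]], ...] = ()
    # parameter name -> element path, carried for the CQL emitter
    param_paths: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        for name, tokens in self.token_params + self.fixed_params:
            if not tokens:
                raise ValueError(f"parameter {name!r} has an empty token list")
        for name, constraints in self.quantity_params:
            if not 1 <= len(constraints) <= 2:
                raise ValueError(
                    f"parameter {name!r}: expected one constraint "
                    "(or a range pair)"
                )

    @property
    def term_tokens(self) -> tuple[TermCode, ...]:
        for name, tokens in self.token_params:
            if name == self.term_param:
                return tokens
        return ()


@dataclass(frozen=True)
class PlanLeaf:
    filter: SearchFilter

    def evaluate(self, leaf_fn: Callable[[SearchFilter], set[str]]) -> set[str]:
        return leaf_fn(self.filter)


@dataclass(frozen=True)
class PlanOp:
    op: str  # UNION | INTERSECT | DIFFERENCE
    children: tuple["PlanNode", ...]

    def __post_init__(self) -> None:
        if self.op not in ("UNION", "INTERSECT", "DIFFERENCE"):
            raise ValueError(f"unknown plan operator {self.op!r}")
        if self.op == "DIFFERENCE" and len(self.children) != 2:
            raise ValueError("DIFFERENCE takes exactly two operands")
        if self.op != "DIFFERENCE" and not self.children:
            raise ValueError(f"{self.op} needs at least one operand")

    def evaluate(self, leaf_fn: Callable[[SearchFilter], set[str]]) -> set[str]:
        results = [child.evaluate(leaf_fn) for child in self.children]
        if self.op == "UNION":
            return set().union(*results)
        if self.op == "INTERSECT":
            out = results[0]
            for r in results[1:]:
                out = out & r
            return out
        return results[0] - results[1]


PlanNode = PlanLeaf | PlanOp


@dataclass(frozen=True)
class QueryPlan:
    """Root of the set-algebra expression; evaluating the root against a
    leaf evaluator yields the cohort's patient-ID set."""

    root: PlanNode

    def evaluate(self, leaf_fn: Callable[[SearchFilter], set[str]]) -> set[str]:
        return self.root.evaluate(leaf_fn)

    def leaves(self) -> list[SearchFilter]:
        out: list[SearchFilter] = []

        def walk(node: PlanNode) -> None:
            if isinstance(node, PlanLeaf):
                out.append(node.filter)
            else:
                for child in node.children:
                    walk(child)

        walk(self.root)
        return out


# ---------------------------------------------------------------------------
# criterion expansion and filtering


def expand_criterion(
    clause: CriterionClause, tree: Sequence[TermTreeNode]
) -> list[TermCode]:
    """Widen each criterion code to itself plus its descendants in the
    terminology tree; codes absent from the tree pass through unchanged."""
    out: list[TermCode] = []
    seen: set[TermCode] = set()
    for wire in clause.term_codes:
        tc = wire.to_term_code()
        expanded = tree_descendants(tree, tc)
        if expanded is None:
            warnings.warn(
                f"code {tc.system}|{tc.code} is not in the terminology "
                "tree; used as-is",
                stacklevel=2,
            )
            expanded = {tc}
        for member in sorted(expanded, key=lambda t: t.key):
            if member not in seen:
                seen.add(member)
                out.append(member)
    return out


def _entry_signature(entry: MappingEntry) -> tuple:
    return (
        entry.resource_type,
        entry.term_code_search_parameter,
        entry.value_search_parameter,
        entry.value_kind,
        entry.fixed_criteria,
    )


def _value_params(
    clause: CriterionClause, entry: MappingEntry
) -> tuple[tuple, tuple]:
    """Render the clause's value filter under the entry's value parameter."""
    vf = clause.value_filter
    if vf is None:
        return (), ()
    if entry.value_kind == "none":
        raise TranslationError(
            f"criterion {entry.key.system}|{entry.key.code} does not "
            "accept a value filter"
        )
    param = entry.value_search_parameter
    assert param is not None
    if isinstance(vf, ConceptFilter):
        if entry.value_kind not in CONCEPT_KINDS:
            raise TranslationError(
                f"criterion {entry.key.code}: concept filter on a "
                f"{entry.value_kind} criterion"
            )
        tokens = tuple(w.to_term_code() for w in vf.selected_concepts)
        return ((param, tokens),), ()
    if entry.value_kind not in QUANTITY_KINDS:
        raise TranslationError(
            f"criterion {entry.key.code}: quantity filter on a "
            f"{entry.value_kind} criterion"
        )
    if isinstance(vf, QuantityComparatorFilter):
        constraints = (QuantityConstraint(vf.comparator, vf.value, vf.unit),)
    elif isinstance(vf, QuantityRangeFilter):
        constraints = (
            QuantityConstraint("ge", vf.min_value, vf.unit),
            QuantityConstraint("le", vf.max_value, vf.unit),
        )
    else:  # pragma: no cover - exhaustive over the union
        raise TranslationError(f"unknown value filter {vf!r}")
    return (), ((param, constraints),)


def criterion_to_search_filters(
    clause: CriterionClause,
    mapping: CriterionMapping,
    tree: Sequence[TermTreeNode],
) -> list[SearchFilter]:
    """One filter per compatible group of the criterion's widened codes.

    Most criteria expand within a single profile and yield one filter; codes
    spanning several resource types or search parameters yield one filter
    per group, to be joined by UNION in the plan.
    """
    expanded = expand_criterion(clause, tree)
    groups: dict[tuple, tuple[MappingEntry, list[TermCode]]] = {}
    for tc in expanded:
        entry = mapping.lookup(tc)
        sig = _entry_signature(entry)
        groups.setdefault(sig, (entry, []))[1].append(tc)
    filters: list[SearchFilter] = []
    for entry, codes in groups.values():
        value_tokens, value_quantities = _value_params(clause, entry)
        paths = [(entry.term_code_search_parameter, entry.term_code_fhir_path)]
        if entry.value_search_parameter and entry.value_fhir_path:
            paths.append((entry.value_search_parameter, entry.value_fhir_path))
        paths.extend(
            (fc.search_parameter, fc.fhir_path) for fc in entry.fixed_criteria
        )
        filters.append(SearchFilter(
            resource_type=entry.resource_type,
            term_param=entry.term_code_search_parameter,
            token_params=(
                (entry.term_code_search_parameter, tuple(codes)),
                *value_tokens,
            ),
            quantity_params=value_quantities,
            fixed_params=tuple(
                (fc.search_parameter, fc.values)
                for fc in entry.fixed_criteria
            ),
            param_paths=tuple(paths),
        ))
    return filters


def criterion_to_search_filter(
    clause: CriterionClause,
    mapping: CriterionMapping,
    tree: Sequence[TermTreeNode],
) -> SearchFilter:
    """Single-filter translation; widened codes spanning incompatible
    mapping entries are an error here."""
    filters = criterion_to_search_filters(clause, mapping, tree)
    if len(filters) != 1:
        params = sorted({(f.resource_type, f.term_param) for f in filters})
        raise HeterogeneousExpansionError(
            f"criterion expands across incompatible entries: {params}"
        )
    return filters[0]


# ---------------------------------------------------------------------------
# plan construction


def _criterion_node(
    clause: CriterionClause,
    mapping: CriterionMapping,
    tree: Sequence[TermTreeNode],
) -> PlanNode:
    filters = criterion_to_search_filters(clause, mapping, tree)
    if len(filters) == 1:
        return PlanLeaf(filters[0])
    return PlanOp("UNION", tuple(PlanLeaf(f) for f in filters))


def sq_to_query_plan(
    sq: StructuredQuery,
    mapping: CriterionMapping,
    tree: Sequence[TermTreeNode],
) -> QueryPlan:
    """Build the plan ``(∩ of ∪ inclusion) ∖ (∪ of ∩ exclusion)``."""
    from .sq import validate_sq

    report = validate_sq(sq)
    if report:
        raise TranslationError("invalid structured query: " + "; ".join(report))
    inclusion = PlanOp("INTERSECT", tuple(
        PlanOp("UNION", tuple(
            _criterion_node(criterion, mapping, tree) for criterion in clause
        ))
        for clause in sq.inclusion
    ))
    if not sq.exclusion:
        return QueryPlan(root=inclusion)
    exclusion = PlanOp("UNION", tuple(
        PlanOp("INTERSECT", tuple(
            _criterion_node(criterion, mapping, tree) for criterion in clause
        ))
        for clause in sq.exclusion
    ))
    return QueryPlan(root=PlanOp("DIFFERENCE", (inclusion, exclusion)))


# ---------------------------------------------------------------------------
# FHIR Search rendering


def _encode(value: str) -> str:
    return urllib.parse.quote(value, safe="")


def _token_component(name: str, tokens: Sequence[TermCode]) -> str:
    rendered = sorted(_encode(f"{tc.system}|{tc.code}") for tc in tokens)
    return f"{name}=" + ",".join(rendered)


def render_fhir_search(filter: SearchFilter) -> str:
    """Render one filter as a GET request string.

    Parameter order is deterministic: the criterion's code parameter first,
    then value parameters, then fixed parameters, each group sorted; tokens
    within a parameter are comma-joined OR alternatives; reserved characters
    are percent-encoded.
    """
    parts: list[str] = []
    term, value_tokens = [], []
    for name, tokens in filter.token_params:
        (term if name == filter.term_param else value_tokens).append(
            _token_component(name, tokens)
        )
    parts.extend(sorted(term))
    value_parts = list(value_tokens)
    for name, constraints in filter.quantity_params:
        for c in constraints:
            value_parts.append(f"{name}=" + _encode(c.render()))
    parts.extend(sorted(value_parts))
    parts.extend(sorted(
        _token_component(name, tokens) for name, tokens in filter.fixed_params
    ))
    return f"{filter.resource_type}?" + "&".join(parts)


def render_plan_requests(plan: QueryPlan) -> list[str]:
    """All leaf requests of a plan, in plan order."""
    return [render_fhir_search(f) for f in plan.leaves()]


# ---------------------------------------------------------------------------
# CQL emission


@dataclass(frozen=True)
class CqlDefine:
    name: str
    filter: SearchFilter

    @property
    def code_set(self) -> frozenset[TermCode]:
        return frozenset(self.filter.term_tokens)


@dataclass
class CqlLibrary:
    defines: list[CqlDefine] = field(default_factory=list)
    population_expression: str = ""

    @property
    def text(self) -> str:
        lines = [
            "library FeasibilityQuery version '1.0.0'",
            "using FHIR version '4.0.1'",
            "context Patient",
            "",
        ]
        for define in self.defines:
            lines.append(f'define "{define.name}":')
            lines.append(_render_define_body(define.filter))
            lines.append("")
        lines.append('define "InInitialPopulation":')
        lines.append(f"  {self.population_expression}")
        lines.append("")
        return "\n".join(lines)


def _cql_path(resource_type: str, fhir_path: str) -> str:
    path = fhir_path.replace(":", ".")
    prefix = resource_type + "."
    if path.startswith(prefix):
        path = path[len(prefix):]
    return "R." + path


def _render_define_body(f: SearchFilter) -> str:
    paths = dict(f.param_paths)
    clauses: list[str] = []
    for name, tokens in f.token_params + f.fixed_params:
        base = _cql_path(f.resource_type, paths.get(name, name))
        codes = ", ".join(
            f"'{tc.code}'" for tc in sorted(tokens, key=lambda t: t.key)
        )
        systems = sorted({tc.system for tc in tokens})
        system_expr = " or ".join(f"system = '{s}'" for s in systems)
        clauses.append(
            f"{base}.coding.where(({system_expr}) and code in {{{codes}}})"
            ".exists()"
        )
    ops = {"eq": "=", "ne": "!=", "le": "<=", "ge": ">=", "lt": "<",
           "gt": ">"}
    for name, constraints in f.quantity_params:
        base = _cql_path(f.resource_type, paths.get(name, name))
        for c in constraints:
            clauses.append(
                f"{base}.value {ops[c.comparator]} {c.value:g} "
                f"and {base}.unit = '{c.unit}'"
            )
    body = "\n      and ".join(clauses) if clauses else "true"
    return f"  exists ([{f.resource_type}] R\n    where {body})"


def sq_to_cql_library(
    sq: StructuredQuery,
    mapping: CriterionMapping,
    tree: Sequence[TermTreeNode],
) -> CqlLibrary:
    """Structured CQL form: defines per criterion plus the population
    expression, kept alongside their filters for cross-emitter checks."""
    plan = sq_to_query_plan(sq, mapping, tree)  # validates the SQ
    del plan
    lib = CqlLibrary()

    def add_criterion(prefix: str, i: int, j: int,
                      clause: CriterionClause) -> str:
        filters = criterion_to_search_filters(clause, mapping, tree)
        names = []
        for k, f in enumerate(filters):
            name = f"{prefix}_{i + 1}_{j + 1}" + (
                f"_{k + 1}" if len(filters) > 1 else ""
            )
            lib.defines.append(CqlDefine(name=name, filter=f))
            names.append(f'"{name}"')
        return names[0] if len(names) == 1 else "(" + " or ".join(names) + ")"

    inclusion_terms = []
    for i, clause in enumerate(sq.inclusion):
        refs = [
            add_criterion("Inclusion", i, j, criterion)
            for j, criterion in enumerate(clause)
        ]
        inclusion_terms.append(
            refs[0] if len(refs) == 1 else "(" + " or ".join(refs) + ")"
        )
    expr = " and ".join(inclusion_terms)
    if sq.exclusion:
        exclusion_terms = []
        for i, clause in enumerate(sq.exclusion):
            refs = [
                add_criterion("Exclusion", i, j, criterion)
                for j, criterion in enumerate(clause)
            ]
            exclusion_terms.append(
                refs[0] if len(refs) == 1 else "(" + " and ".join(refs) + ")"
            )
        excl = " or ".join(exclusion_terms)
        expr = f"({expr}) and not ({excl})"
    lib.population_expression = expr
    return lib


def sq_to_cql(
    sq: StructuredQuery,
    mapping: CriterionMapping,
    tree: Sequence[TermTreeNode],
) -> str:
    """CQL library text for an SQ (see :func:`sq_to_cql_library`)."""
    return sq_to_cql_library(sq, mapping, tree).text
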