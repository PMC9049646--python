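"""UI-profile generation: from profiles + terminology to a criteria ontology.

Profiles are grouped by FHIR ResourceType and handled by a per-type default
handler that knows which attribute specifies the criteria (``Condition.code``,
``Immunization.vaccineCode``, ...) and which, if any, specifies a value.
Profiles that deviate from their type's default layout — an integer-valued
score, information held in a component slice, an extension — are routed by a
corner-case registry consulted before the defaults.

For each criterion profile, the binding of the criteria-specifying attribute
is expanded, reduced to a single code system (overlapping concepts such as
sleep apnea exist in both ICD-10-GM and SNOMED CT; showing one system avoids
duplicated criteria), shaped into a tree along the is-a subsumption
relations, and appended below a non-selectable group node named after the
criterion.  Every concept node is selectable and carries the profile's value
definition, if any.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

from .artifacts import (
    CategorySpec,
    ElementModel,
    ProfileModel,
    TermCode,
    element_by_path,
)
from .errors import (
    ElementNotFoundError,
    FeasQueryError,
    GenerationError,
    UnsupportedResourceTypeError,
)
from .systems import CRITERION_GROUP, DEFAULT_PREFERENCE, UCUM
from .terminology import (
    Expansion,
    SubsumptionForest,
    build_subsumption_forest,
    expand_value_set,
)

__all__ = [
    "HandlerSpec",
    "ValueDefinition",
    "UIProfileNode",
    "CategoryTree",
    "GenerationReport",
    "TerminologyService",
    "DEFAULT_HANDLERS",
    "default_corner_case_registry",
    "DEFAULT_DENY_LIST",
    "classify_profile",
    "select_code_system",
    "generate_criteria_nodes",
    "generate_ui_profiles",
    "iter_selectable_nodes",
    "category_trees_to_json",
]

VALUE_KINDS = (
    "none",
    "concept",
    "quantity",
    "component-concept",
    "component-quantity",
    "integer-score",
    "conclusion-text",
)

#: Comparators offered for quantity criteria; units are matched verbatim
#: (no conversion between unit dimensions).
QUANTITY_COMPARATORS = ("eq", "ne", "le", "ge", "lt", "gt")


@dataclass(frozen=True)
class HandlerSpec:
    """How one profile (or one ResourceType) is turned into criteria."""

    handler_id: str
    resource_type: str
    criterion_attr: str
    value_attr: str | None = None
    value_kind: str = "none"

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if (self.value_kind == "none") != (self.value_attr is None):
            raise ValueError(
                f"handler {self.handler_id!r}: value_kind 'none' "
                "iff value_attr absent"
            )


@dataclass(frozen=True)
class ValueDefinition:
    """What a criterion's optional value restriction looks like in the UI."""

    kind: str  # "concept" | "quantity"
    selectable_concepts: tuple[TermCode, ...] = ()
    allowed_units: tuple[str, ...] = ()
    comparators: tuple[str, ...] = QUANTITY_COMPARATORS

    def __post_init__(self) -> None:
        if self.kind == "concept" and not self.selectable_concepts:
            raise ValueError("concept value definition without concepts")
        if self.kind == "quantity" and not self.allowed_units:
            raise ValueError("quantity value definition without units")
        if self.kind not in ("concept", "quantity"):
            raise ValueError(f"unknown value definition kind {self.kind!r}")

    def to_json(self) -> dict:
        if self.kind == "concept":
            return {
                "kind": "concept",
                "selectableConcepts": [
                    tc.to_json() for tc in self.selectable_concepts
                ],
            }
        return {
            "kind": "quantity",
            "allowedUnits": list(self.allowed_units),
            "comparators": list(self.comparators),
        }


@dataclass
class UIProfileNode:
    """One node of the criteria ontology shown to the researcher.

    A node with an empty ``children`` list is a leaf criterion; a non-leaf
    stands for itself plus everything that descends from it.
    """

    term_code: TermCode
    display: str
    selectable: bool
    children: list["UIProfileNode"] = field(default_factory=list)
    value_definition: ValueDefinition | None = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def to_json(self) -> dict:
        return {
            "termCode": self.term_code.to_json(),
            "display": self.display,
            "selectable": self.selectable,
            "children": [c.to_json() for c in self.children],
            "valueDefinition": (
                self.value_definition.to_json()
                if self.value_definition is not None
                else None
            ),
        }


@dataclass
class CategoryTree:
    category_name: str
    roots: list[UIProfileNode] = field(default_factory=list)

    def to_json(self) -> dict:
        return {
            "categoryName": self.category_name,
            "roots": [r.to_json() for r in self.roots],
        }


@dataclass
class GenerationReport:
    """Per-run account of what was generated, skipped, or failed."""

    unresolved_criteria: list[str] = field(default_factory=list)
    denied_criteria: list[str] = field(default_factory=list)
    failures: list[tuple[str, str]] = field(default_factory=list)  # (name, why)
    warnings: list[str] = field(default_factory=list)
    generated_criteria: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.failures

    def to_text(self) -> str:
        lines = [
            f"criteria generated: {len(self.generated_criteria)}",
            f"unresolved criterion names: {len(self.unresolved_criteria)}",
            f"excluded by deny list: {len(self.denied_criteria)}",
            f"failures: {len(self.failures)}",
        ]
        for name in self.unresolved_criteria:
            lines.append(f"  unresolved: {name}")
        for name in self.denied_criteria:
            lines.append(f"  denied: {name}")
        for name, why in self.failures:
            lines.append(f"  failed: {name}: {why}")
        for msg in self.warnings:
            lines.append(f"  warning: {msg}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# handlers

DEFAULT_HANDLERS: dict[str, HandlerSpec] = {
    "Condition": HandlerSpec(
        "default-condition", "Condition", "Condition.code"
    ),
    # Observation defaults are a template: concept vs quantity is decided per
    # profile by the constrained type of Observation.value[x].
    "Observation": HandlerSpec(
        "default-observation-concept",
        "Observation",
        "Observation.code",
        "Observation.value[x]",
        "concept",
    ),
    "Procedure": HandlerSpec(
        "default-procedure", "Procedure", "Procedure.code"
    ),
    "MedicationStatement": HandlerSpec(
        "default-medication-statement",
        "MedicationStatement",
        "MedicationStatement.medication[x]",
    ),
    "Immunization": HandlerSpec(
        "default-immunization", "Immunization", "Immunization.vaccineCode"
    ),
    "DiagnosticReport": HandlerSpec(
        "default-diagnostic-report",
        "DiagnosticReport",
        "DiagnosticReport.code",
        "DiagnosticReport.conclusionCode",
        "conclusion-text",
    ),
    "Specimen": HandlerSpec(
        "default-specimen", "Specimen", "Specimen.type"
    ),
}


def default_corner_case_registry() -> dict[str, HandlerSpec]:
    """The seven explicit handlers for profiles the per-type defaults cannot
    cover (blood pressure counts once per component, systolic and diastolic).
    """
    specs = [
        # score kept in value[integer], not value[quantity]
        HandlerSpec(
            "corner-sofa", "Observation", "Observation.code",
            "Observation.value[x]", "integer-score",
        ),
        # concept of interest lives in a component slice
        HandlerSpec(
            "corner-history-of-travel", "Observation", "Observation.code",
            "Observation.component:travel.value[x]", "component-concept",
        ),
        # quantity of interest lives in a component slice
        HandlerSpec(
            "corner-systolic-bp", "Observation", "Observation.code",
            "Observation.component:systolic.value[x]", "component-quantity",
        ),
        HandlerSpec(
            "corner-diastolic-bp", "Observation", "Observation.code",
            "Observation.component:diastolic.value[x]", "component-quantity",
        ),
        # symptom severity settable as a value by the researcher
        HandlerSpec(
            "corner-covid19-symptoms", "Condition", "Condition.code",
            "Condition.severity", "concept",
        ),
        # extensions need custom search parameters and FHIR paths
        HandlerSpec(
            "corner-ethnic-group", "Patient",
            "Patient.extension:ethnicGroup.value[x]",
        ),
        HandlerSpec(
            "corner-age", "Patient", "Patient.extension:age.code",
            "Patient.extension:age.value[x]", "quantity",
        ),
    ]
    by_profile_name = {
        "SOFA": specs[0],
        "HistoryOfTravel": specs[1],
        "SystolicBloodPressure": specs[2],
        "DiastolicBloodPressure": specs[3],
        "Covid19Symptoms": specs[4],
        "EthnicGroup": specs[5],
        "Age": specs[6],
    }
    return by_profile_name


#: Criterion names never generated; the birth date would allow re-identifying
#: patients from feasibility counts.
DEFAULT_DENY_LIST = frozenset({"DateOfBirth"})


def classify_profile(
    profile: ProfileModel,
    registry: Mapping[str, HandlerSpec] | None = None,
) -> HandlerSpec:
    """Pick the handler for a profile: corner-case registry first (matched by
    profile name or canonical URL), then the ResourceType default."""
    if registry is None:
        registry = default_corner_case_registry()
    spec = registry.get(profile.name) or registry.get(profile.url)
    if spec is not None:
        return spec
    spec = DEFAULT_HANDLERS.get(profile.resource_type)
    if spec is None:
        raise UnsupportedResourceTypeError(
            f"profile {profile.name!r}: no default handler and no corner case "
            f"for resource type {profile.resource_type!r}"
        )
    if profile.resource_type == "Observation":
        return _disambiguate_observation(profile, spec)
    return spec


def _disambiguate_observation(
    profile: ProfileModel, template: HandlerSpec
) -> HandlerSpec:
    try:
        value_el = element_by_path(profile, "Observation.value[x]")
    except ElementNotFoundError:
        return replace(
            template, handler_id="default-observation-code-only",
            value_attr=None, value_kind="none",
        )
    if value_el.type_code == "Quantity":
        return replace(
            template, handler_id="default-observation-quantity",
            value_kind="quantity",
        )
    return template


# ---------------------------------------------------------------------------
# terminology service


@dataclass
class TerminologyService:
    """Bundles ValueSet expansion and forest building for generation.

    ``expander`` defaults to local expansion over the artifact set; a
    terminology-server client with the same contract can be dropped in.
    """

    value_sets: Mapping[str, object]
    code_systems: Mapping[str, object]
    expander: object | None = None

    def expand(self, value_set_url: str) -> Expansion:
        if self.expander is not None:
            return self.expander.expand(value_set_url)  # type: ignore[attr-defined]
        vs = self.value_sets.get(value_set_url)
        if vs is None:
            raise GenerationError(f"unknown ValueSet {value_set_url}")
        return expand_value_set(vs, self.code_systems)  # type: ignore[arg-type]

    def forest(self, exp: Expansion) -> SubsumptionForest:
        return build_subsumption_forest(exp, self.code_systems)  # type: ignore[arg-type]


# ---------------------------------------------------------------------------
# generation


def select_code_system(
    exp: Expansion, preference: Sequence[str] = DEFAULT_PREFERENCE
) -> Expansion:
    """Keep only the highest-preference system present in the expansion."""
    if not preference:
        raise ValueError("empty code-system preference")
    present = set(exp.systems)
    for system in preference:
        if system in present:
            kept = [tc for tc in exp.concepts if tc.system == system]
            return Expansion(value_set_url=exp.value_set_url, concepts=kept)
    if present:
        warnings.warn(
            f"expansion of {exp.value_set_url} spans no preferred system; "
            "keeping all concepts",
            stacklevel=2,
        )
    return Expansion(value_set_url=exp.value_set_url, concepts=list(exp.concepts))


def _unit_for(profile: ProfileModel, value_el: ElementModel) -> str:
    """Unit code of a quantity element, from the fixed ``.code`` child."""
    for el in profile.elements:
        if el.path == value_el.path + ".code" and el.fixed_value is not None:
            return str(el.fixed_value)
    return "1"  # UCUM dimensionless (e.g. scores)


def _build_value_definition(
    profile: ProfileModel, handler: HandlerSpec, term: TerminologyService
) -> ValueDefinition | None:
    if handler.value_kind == "none":
        return None
    value_el = element_by_path(profile, handler.value_attr)  # type: ignore[arg-type]
    if handler.value_kind in ("concept", "component-concept", "conclusion-text"):
        if value_el.binding_url is None:
            raise GenerationError(
                f"profile {profile.name!r}: value attribute "
                f"{handler.value_attr!r} has no binding"
            )
        exp = term.expand(value_el.binding_url)
        return ValueDefinition(
            kind="concept", selectable_concepts=tuple(exp.concepts)
        )
    # quantity-like: quantity, component-quantity, integer-score
    unit = "1" if handler.value_kind == "integer-score" else _unit_for(
        profile, value_el
    )
    return ValueDefinition(kind="quantity", allowed_units=(unit,))


def _forest_to_nodes(
    forest: SubsumptionForest, value_definition: ValueDefinition | None
) -> list[UIProfileNode]:
    def render(tc: TermCode) -> UIProfileNode:
        # multi-parent concepts are rendered once under each parent: tree
        # formats cannot share nodes, duplication preserves findability
        return UIProfileNode(
            term_code=tc,
            display=tc.display,
            selectable=True,
            children=[render(c) for c in forest.children_of(tc)],
            value_definition=value_definition,
        )

    return [render(root) for root in forest.roots]


def generate_criteria_nodes(
    profile: ProfileModel,
    handler: HandlerSpec,
    term: TerminologyService,
    preference: Sequence[str] = DEFAULT_PREFERENCE,
) -> list[UIProfileNode]:
    """Expand the criterion binding and shape it into selectable nodes."""
    criterion_el = element_by_path(profile, handler.criterion_attr)
    if criterion_el.binding_url is None:
        raise GenerationError(
            f"profile {profile.name!r}: criteria-specifying attribute "
            f"{handler.criterion_attr!r} has no binding"
        )
    exp = select_code_system(term.expand(criterion_el.binding_url), preference)
    if not exp.concepts:
        warnings.warn(
            f"profile {profile.name!r}: empty expansion after code-system "
            "filtering",
            stacklevel=2,
        )
        return []
    value_definition = _build_value_definition(profile, handler, term)
    return _forest_to_nodes(term.forest(exp), value_definition)


def generate_ui_profiles(
    categories: Sequence[CategorySpec],
    profiles: Mapping[str, ProfileModel],
    term: TerminologyService,
    *,
    registry: Mapping[str, HandlerSpec] | None = None,
    preference: Sequence[str] = DEFAULT_PREFERENCE,
    deny_list: frozenset[str] = DEFAULT_DENY_LIST,
) -> tuple[list[CategoryTree], GenerationReport]:
    """Render every category of the LogicalModel into a criteria tree.

    Per-criterion failures are collected in the report instead of aborting
    the run; unresolved criterion names (no matching profile) are reported.
    """
    if registry is None:
        registry = default_corner_case_registry()
    report = GenerationReport()
    trees: list[CategoryTree] = []
    for category in categories:
        tree = CategoryTree(category_name=category.name)
        for name in category.criterion_names:
            if name in deny_list:
                report.denied_criteria.append(name)
                continue
            profile = profiles.get(name)
            if profile is None:
                report.unresolved_criteria.append(name)
                continue
            try:
                handler = classify_profile(profile, registry)
                children = generate_criteria_nodes(
                    profile, handler, term, preference
                )
            except FeasQueryError as exc:
                report.failures.append((name, str(exc)))
                continue
            group = UIProfileNode(
                term_code=TermCode(
                    system=CRITERION_GROUP, code=name, display=name
                ),
                display=name,
                selectable=False,
                children=children,
            )
            tree.roots.append(group)
            report.generated_criteria.append(name)
        trees.append(tree)
    return trees, report


def iter_selectable_nodes(
    trees: Sequence[CategoryTree],
) -> Iterator[UIProfileNode]:
    def walk(node: UIProfileNode) -> Iterator[UIProfileNode]:
        if node.selectable:
            yield node
        for child in node.children:
            yield from walk(child)

    for tree in trees:
        for root in tree.roots:
            yield from walk(root)


def category_trees_to_json(trees: Sequence[CategoryTree]) -> list[dict]:
    return [tree.to_json() for tree in trees]
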