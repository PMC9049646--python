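"""Synthetic conformance artifacts, patient data, and brute-force oracles.

This module is first-class, tested code, not an afterthought: it emulates
the input side of the generation pipeline (a LogicalModel with categories
and criteria, per-ResourceType profiles with bindings, CodeSystems with
is-a hierarchies across several terminologies) and the data side (a store
of patient-level resource instances conforming to those profiles), plus the
independent evaluators used as oracles for the whole translation chain.

The fixed *roster* of profiles covers every ResourceType the default
handlers know (Condition, Observation in concept and quantity flavours,
Procedure, MedicationStatement, Immunization, DiagnosticReport, Specimen)
and every corner case (SOFA's value[integer], the History-of-Travel and
blood-pressure components, symptom severity, the ethnic-group and age
extensions), a mixed ICD-10-GM/SNOMED ValueSet to exercise the
single-CodeSystem preference rule, and a deny-listed date-of-birth
criterion.  Synthetic resources are flat records keyed by dotted FHIR path
— the evaluators need only the mapped paths, full FHIR instances would add
no test power.

All generation is a pure function of the seed.  The brute-force SQ
evaluator shares no code with the query-plan machinery beyond the domain
types; the fault injector reproduces the four discrepancy classes observed
between independently produced test data and a generated ontology: version
drift in concept coding, unit mismatch, codes from a non-displayed code
system, and subset (postcoordinated) coding.
"""

from __future__ import annotations

import copy
import math
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .artifacts import (
    ArtifactSet,
    CategorySpec,
    CodeSystemModel,
    ElementModel,
    IncludeRule,
    ProfileModel,
    TermCode,
    ValueSetModel,
)
from .errors import EvaluationError, UnmappedCriterionError
from .mapping import CriterionMapping, MappingEntry, TermTreeNode
from .ontology import ValueDefinition, iter_selectable_nodes
from .pipeline import GenerationResult, run_generation
from .sq import (
    ConceptFilter,
    CriterionClause,
    QuantityComparatorFilter,
    QuantityRangeFilter,
    StructuredQuery,
    WireTermCode,
)
from .systems import ATC, CONDITION_VER_STATUS, ICD10GM, LOINC, SNOMED
from .translate import SearchFilter

__all__ = [
    "FixtureSpec",
    "StoredResource",
    "ResourceStore",
    "TestQueryCase",
    "SuiteReport",
    "gen_artifacts",
    "write_artifact_directory",
    "gen_patients",
    "eval_filter",
    "eval_sq_bruteforce",
    "build_criterion_test_suite",
    "run_suite",
    "inject_faults",
    "generate_random_sq",
    "FAULT_CLASSES",
]

VS_BASE = "http://feasquery.local/ValueSet/"
SD_BASE = "http://feasquery.local/StructureDefinition/"
SYNTH_CS_BASE = "http://feasquery.local/CodeSystem/synthetic-"

FAULT_CLASSES = (
    "version-drift", "unit-mismatch", "missing-system", "subset-coding",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of one synthetic study: terminology, ontology and population.

    Defaults give a GECCO-like desk-scale study: the full roster of
    ResourceType and corner-case profiles spread over four categories,
    two synthetic code systems feeding extra Condition criteria, 200
    patients, and criterion prevalence of 20% so that single-criterion
    cohorts average ~40 patients.  Quantity values are drawn uniformly on
    a band centered on ``quantity_threshold`` so every comparator branch
    sees matches and non-matches.
    """

    seed: int = 0
    n_systems: int = 2
    codes_per_system: int = 24
    max_children: int = 3
    n_categories: int = 4
    profiles_per_category: int = 5
    n_patients: int = 200
    criterion_prevalence: float = 0.2
    quantity_threshold: float = 50.0
    quantity_halfwidth: float = 30.0
    unconfirmed_rate: float = 0.1
    include_roster: bool = True

    def __post_init__(self) -> None:
        for name in ("n_systems", "codes_per_system", "max_children",
                     "n_categories", "profiles_per_category", "n_patients"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.criterion_prevalence <= 1.0:
            raise ValueError("criterion_prevalence must be in [0, 1]")

    @property
    def quantity_range(self) -> tuple[float, float]:
        return (
            self.quantity_threshold - self.quantity_halfwidth,
            self.quantity_threshold + self.quantity_halfwidth,
        )


# ---------------------------------------------------------------------------
# roster artifacts (fixed content)


def _cs(url: str, concepts: dict[str, str],
        edges: Iterable[tuple[str, str]] = ()) -> CodeSystemModel:
    return CodeSystemModel(url=url, concepts=dict(concepts),
                           parent_edges=list(edges))


def _roster_code_systems() -> dict[str, CodeSystemModel]:
    icd = _cs(ICD10GM, {
        "J40-J47": "Chronic lower respiratory diseases",
        "J44": "Chronic obstructive pulmonary disease",
        "J44.0": "COPD with acute lower respiratory infection",
        "J44.1": "COPD with acute exacerbation",
        "J45": "Asthma",
        "J45.0": "Predominantly allergic asthma",
        "J47": "Bronchiectasis",
        "G47.3": "Sleep apnoea",
    }, [
        ("J44", "J40-J47"), ("J45", "J40-J47"), ("J47", "J40-J47"),
        ("J44.0", "J44"), ("J44.1", "J44"), ("J45.0", "J45"),
    ])
    snomed = _cs(SNOMED, {
        # chronic lung disease (overlaps ICD-10-GM; filtered from the UI)
        "413839001": "Chronic lung disease",
        "13645005": "Chronic obstructive lung disease",
        "195967001": "Asthma",
        # symptoms
        "272044004": "Symptom finding",
        "49727002": "Cough",
        "11833005": "Dry cough",
        "28743005": "Productive cough",
        "386661006": "Fever",
        "267036007": "Dyspnea",
        # severity values
        "255604002": "Mild",
        "6736007": "Moderate",
        "24484000": "Severe",
        # sex values
        "248152002": "Female",
        "248153007": "Male",
        # procedures
        "363679005": "Imaging",
        "168537006": "Plain radiography",
        "399208008": "Plain chest X-ray",
        "77477000": "Computed tomography of thorax",
        # vaccines
        "787859002": "Vaccine product",
        "1119305005": "COVID-19 antigen vaccine",
        "871875004": "COVID-19 mRNA vaccine",
        # report conclusions
        "263654008": "Abnormal",
        "281900007": "No abnormality detected",
        # travel destinations
        "276826009": "Germany",
        "223688001": "United States of America",
        "223566001": "China",
        # specimens
        "123038009": "Specimen",
        "119297000": "Blood specimen",
        "119361006": "Plasma specimen",
        # ethnic groups
        "14045001": "Caucasian",
        "186019001": "Other ethnic group",
        # age
        "424144002": "Current chronological age",
    }, [
        ("13645005", "413839001"), ("195967001", "413839001"),
        ("49727002", "272044004"), ("386661006", "272044004"),
        ("267036007", "272044004"),
        ("11833005", "49727002"), ("28743005", "49727002"),
        ("168537006", "363679005"), ("77477000", "363679005"),
        ("399208008", "168537006"),
        ("1119305005", "787859002"), ("871875004", "787859002"),
        ("119297000", "123038009"), ("119361006", "123038009"),
    ])
    loinc = _cs(LOINC, {
        "29463-7": "Body weight",
        "76689-9": "Sex assigned at birth",
        "92797-3": "SOFA total score",
        "8691-8": "History of travel",
        "8480-6": "Systolic blood pressure",
        "8462-4": "Diastolic blood pressure",
        "18748-4": "Diagnostic imaging study",
        "21112-8": "Birth date",
    })
    atc = _cs(ATC, {
        "N02": "Analgesics",
        "N02B": "Other analgesics and antipyretics",
        "N02BA": "Salicylic acid and derivatives",
        "N02BA01": "Acetylsalicylic acid",
        "N02BE": "Anilides",
        "N02BE01": "Paracetamol",
    }, [
        ("N02B", "N02"), ("N02BA", "N02B"), ("N02BE", "N02B"),
        ("N02BA01", "N02BA"), ("N02BE01", "N02BE"),
    ])
    return {cs.url: cs for cs in (icd, snomed, loinc, atc)}


def _vs(name: str, rules: list[IncludeRule]) -> ValueSetModel:
    return ValueSetModel(url=VS_BASE + name, include_rules=rules)


def _roster_value_sets() -> dict[str, ValueSetModel]:
    sets = [
        _vs("chronic-lung-disease", [
            IncludeRule(system=ICD10GM, filter_anchor="J40-J47"),
            IncludeRule(system=ICD10GM, codes=("G47.3",)),
            IncludeRule(system=SNOMED, filter_anchor="413839001"),
        ]),
        _vs("covid19-symptoms", [
            IncludeRule(system=SNOMED, filter_anchor="272044004"),
        ]),
        _vs("severity", [
            IncludeRule(system=SNOMED,
                        codes=("255604002", "6736007", "24484000")),
        ]),
        _vs("sex-code", [IncludeRule(system=LOINC, codes=("76689-9",))]),
        _vs("sex-values", [
            IncludeRule(system=SNOMED, codes=("248152002", "248153007")),
        ]),
        _vs("body-weight-code", [IncludeRule(system=LOINC, codes=("29463-7",))]),
        _vs("sofa-code", [IncludeRule(system=LOINC, codes=("92797-3",))]),
        _vs("history-of-travel-code", [
            IncludeRule(system=LOINC, codes=("8691-8",)),
        ]),
        _vs("travel-destinations", [
            IncludeRule(system=SNOMED,
                        codes=("276826009", "223688001", "223566001")),
        ]),
        _vs("systolic-bp-code", [IncludeRule(system=LOINC, codes=("8480-6",))]),
        _vs("diastolic-bp-code", [IncludeRule(system=LOINC, codes=("8462-4",))]),
        _vs("procedures", [
            IncludeRule(system=SNOMED, filter_anchor="363679005"),
        ]),
        _vs("antipyretics", [IncludeRule(system=ATC, filter_anchor="N02")]),
        _vs("vaccines", [
            IncludeRule(system=SNOMED, filter_anchor="787859002"),
        ]),
        _vs("report-code", [IncludeRule(system=LOINC, codes=("18748-4",))]),
        _vs("report-conclusions", [
            IncludeRule(system=SNOMED, codes=("263654008", "281900007")),
        ]),
        _vs("specimen-types", [
            IncludeRule(system=SNOMED, filter_anchor="123038009"),
        ]),
        _vs("ethnic-groups", [
            IncludeRule(system=SNOMED, codes=("14045001", "186019001")),
        ]),
        _vs("age-code", [IncludeRule(system=SNOMED, codes=("424144002",))]),
        _vs("dob-code", [IncludeRule(system=LOINC, codes=("21112-8",))]),
    ]
    return {vs.url: vs for vs in sets}


def _el(path: str, type_code: str = "", binding: str | None = None,
        fixed: object = None) -> ElementModel:
    return ElementModel(path=path, type_code=type_code, binding_url=binding,
                        fixed_value=fixed)


def _profile(name: str, resource_type: str,
             elements: list[ElementModel]) -> ProfileModel:
    root = _el(resource_type)
    return ProfileModel(url=SD_BASE + name, name=name,
                        resource_type=resource_type,
                        elements=[root, *elements])


def _roster_profiles() -> list[ProfileModel]:
    v = VS_BASE
    return [
        _profile("ChronicLungDisease", "Condition", [
            _el("Condition.code", "CodeableConcept",
                v + "chronic-lung-disease"),
            _el("Condition.verificationStatus", "CodeableConcept"),
        ]),
        _profile("Covid19Symptoms", "Condition", [
            _el("Condition.code", "CodeableConcept", v + "covid19-symptoms"),
            _el("Condition.severity", "CodeableConcept", v + "severity"),
            _el("Condition.verificationStatus", "CodeableConcept"),
        ]),
        _profile("SexAssignedAtBirth", "Observation", [
            _el("Observation.code", "CodeableConcept", v + "sex-code"),
            _el("Observation.valueCodeableConcept", "CodeableConcept",
                v + "sex-values"),
        ]),
        _profile("BodyWeight", "Observation", [
            _el("Observation.code", "CodeableConcept", v + "body-weight-code"),
            _el("Observation.valueQuantity", "Quantity"),
            _el("Observation.valueQuantity.code", "code", fixed="kg"),
        ]),
        _profile("SOFA", "Observation", [
            _el("Observation.code", "CodeableConcept", v + "sofa-code"),
            _el("Observation.valueInteger", "integer"),
        ]),
        _profile("HistoryOfTravel", "Observation", [
            _el("Observation.code", "CodeableConcept",
                v + "history-of-travel-code"),
            _el("Observation.component:travel.code", "Coding",
                fixed={"system": LOINC, "code": "8691-8",
                       "display": "History of travel"}),
            _el("Observation.component:travel.valueCodeableConcept",
                "CodeableConcept", v + "travel-destinations"),
        ]),
        _profile("SystolicBloodPressure", "Observation", [
            _el("Observation.code", "CodeableConcept", v + "systolic-bp-code"),
            _el("Observation.component:systolic.code", "Coding",
                fixed={"system": LOINC, "code": "8480-6",
                       "display": "Systolic blood pressure"}),
            _el("Observation.component:systolic.valueQuantity", "Quantity"),
            _el("Observation.component:systolic.valueQuantity.code", "code",
                fixed="mm[Hg]"),
        ]),
        _profile("DiastolicBloodPressure", "Observation", [
            _el("Observation.code", "CodeableConcept", v + "diastolic-bp-code"),
            _el("Observation.component:diastolic.code", "Coding",
                fixed={"system": LOINC, "code": "8462-4",
                       "display": "Diastolic blood pressure"}),
            _el("Observation.component:diastolic.valueQuantity", "Quantity"),
            _el("Observation.component:diastolic.valueQuantity.code", "code",
                fixed="mm[Hg]"),
        ]),
        _profile("RadiologyProcedures", "Procedure", [
            _el("Procedure.code", "CodeableConcept", v + "procedures"),
        ]),
        _profile("AntipyreticMedication", "MedicationStatement", [
            _el("MedicationStatement.medicationCodeableConcept",
                "CodeableConcept", v + "antipyretics"),
        ]),
        _profile("Vaccination", "Immunization", [
            _el("Immunization.vaccineCode", "CodeableConcept", v + "vaccines"),
        ]),
        _profile("RadiologyReport", "DiagnosticReport", [
            _el("DiagnosticReport.code", "CodeableConcept", v + "report-code"),
            _el("DiagnosticReport.conclusionCode", "CodeableConcept",
                v + "report-conclusions"),
        ]),
        _profile("BloodSpecimen", "Specimen", [
            _el("Specimen.type", "CodeableConcept", v + "specimen-types"),
        ]),
        _profile("EthnicGroup", "Patient", [
            _el("Patient.extension:ethnicGroup.valueCoding", "Coding",
                v + "ethnic-groups"),
        ]),
        _profile("Age", "Patient", [
            _el("Patient.extension:age.code", "Coding", v + "age-code"),
            _el("Patient.extension:age.valueQuantity", "Quantity"),
            _el("Patient.extension:age.valueQuantity.code", "code", fixed="a"),
        ]),
        _profile("DateOfBirth", "Observation", [
            _el("Observation.code", "CodeableConcept", v + "dob-code"),
        ]),
    ]


_CATEGORY_NAMES = (
    "AnamnesisRiskFactors", "Demographics", "SymptomsFindings",
    "TherapyVitalSigns",
)


# ---------------------------------------------------------------------------
# artifact generation


def gen_artifacts(spec: FixtureSpec) -> ArtifactSet:
    """Deterministically generate a full conformance-artifact set."""
    rng = random.Random(spec.seed)
    code_systems: dict[str, CodeSystemModel] = {}
    value_sets: dict[str, ValueSetModel] = {}
    profiles: dict[str, ProfileModel] = {}
    roster_names: list[str] = []

    if spec.include_roster:
        code_systems.update(_roster_code_systems())
        value_sets.update(_roster_value_sets())
        for profile in _roster_profiles():
            profiles[profile.name] = profile
            roster_names.append(profile.name)

    # synthetic systems feeding extra Condition criteria
    total_slots = spec.n_categories * spec.profiles_per_category
    n_extra = max(0, total_slots - len(roster_names))
    synth: list[CodeSystemModel] = []
    for k in range(spec.n_systems):
        codes = [f"S{k}-{j:03d}" for j in range(spec.codes_per_system)]
        concepts = {c: f"Synthetic concept {c}" for c in codes}
        edges: list[tuple[str, str]] = []
        child_count: dict[str, int] = {}
        for j, code in enumerate(codes[1:], start=1):
            if rng.random() < 0.7:
                candidates = [
                    p for p in codes[:j]
                    if child_count.get(p, 0) < spec.max_children
                ]
                if candidates:
                    parent = rng.choice(candidates)
                    edges.append((code, parent))
                    child_count[parent] = child_count.get(parent, 0) + 1
        cs = _cs(SYNTH_CS_BASE + str(k), concepts, edges)
        synth.append(cs)
        code_systems[cs.url] = cs

    extra_names: list[str] = []
    if n_extra:
        per_system = math.ceil(n_extra / spec.n_systems)
        chunk = max(1, spec.codes_per_system // per_system)
        for i in range(n_extra):
            cs = synth[i % spec.n_systems]
            codes = sorted(cs.concepts)
            start = (i // spec.n_systems) * chunk
            block = codes[start: start + chunk] or codes[-1:]
            name = f"SyntheticCondition{i:02d}"
            vs = _vs(f"synthetic-{i:02d}", [
                IncludeRule(system=cs.url, codes=tuple(block)),
            ])
            value_sets[vs.url] = vs
            profiles[name] = _profile(name, "Condition", [
                _el("Condition.code", "CodeableConcept", vs.url),
                _el("Condition.verificationStatus", "CodeableConcept"),
            ])
            extra_names.append(name)

    all_names = roster_names + extra_names
    categories: list[CategorySpec] = []
    for c in range(spec.n_categories):
        name = (_CATEGORY_NAMES[c] if c < len(_CATEGORY_NAMES)
                else f"Category{c:02d}")
        categories.append(CategorySpec(name=name))
    for i, profile_name in enumerate(all_names):
        categories[i % spec.n_categories].criterion_names.append(profile_name)

    return ArtifactSet(
        categories=categories, profiles=profiles,
        value_sets=value_sets, code_systems=code_systems,
    )


def _logical_model_document(categories: Sequence[CategorySpec]) -> dict:
    elements = [{"path": "FeasModel"}]
    for cat in categories:
        elements.append({"path": f"FeasModel.{cat.name}"})
        for crit in cat.criterion_names:
            elements.append({"path": f"FeasModel.{cat.name}.{crit}"})
    return {
        "resourceType": "StructureDefinition",
        "url": SD_BASE + "FeasModel",
        "name": "FeasModel",
        "status": "active",
        "kind": "logical",
        "abstract": True,
        "type": "FeasModel",
        "differential": {"element": elements},
    }


def write_artifact_directory(artifacts: ArtifactSet, out_dir: str | Path) -> None:
    """Write the conventional layout consumed by
    :func:`feasquery.artifacts.load_artifact_directory`."""
    import json

    out = Path(out_dir)
    for sub in ("profiles", "valuesets", "codesystems"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    def dump(doc: dict, path: Path) -> None:
        path.write_text(json.dumps(doc, indent=2, ensure_ascii=False) + "\n",
                        encoding="utf-8")

    dump(_logical_model_document(artifacts.categories),
         out / "logicalmodel.json")
    for name, profile in sorted(artifacts.profiles.items()):
        dump(profile.to_structure_definition(),
             out / "profiles" / f"{name}.json")
    for url, vs in sorted(artifacts.value_sets.items()):
        dump(vs.to_document(), out / "valuesets" / f"{url.rsplit('/', 1)[-1]}.json")
    for i, (url, cs) in enumerate(sorted(artifacts.code_systems.items())):
        dump(cs.to_document(), out / "codesystems" / f"cs-{i:02d}.json")


# ---------------------------------------------------------------------------
# patient data


@dataclass
class StoredResource:
    """A flat resource record: coded and quantity fields keyed by path."""

    resource_type: str
    patient: str
    coded: dict[str, TermCode] = field(default_factory=dict)
    quantities: dict[str, tuple[float, str]] = field(default_factory=dict)


@dataclass
class ResourceStore:
    """Patient-level instance data plus the search-parameter schema of the
    simulated FHIR server (parameter -> element path per resource type)."""

    patients: list[str] = field(default_factory=list)
    resources: list[StoredResource] = field(default_factory=list)
    param_paths: dict[tuple[str, str], str] = field(default_factory=dict)
    quantity_range: tuple[float, float] = (20.0, 80.0)

    def resources_of(self, resource_type: str) -> list[StoredResource]:
        return [r for r in self.resources if r.resource_type == resource_type]


CONFIRMED_TC = TermCode(CONDITION_VER_STATUS, "confirmed", "Confirmed")
PROVISIONAL_TC = TermCode(CONDITION_VER_STATUS, "provisional", "Provisional")


def _value_definitions(generated: GenerationResult
                       ) -> dict[tuple[str, str], ValueDefinition | None]:
    out: dict[tuple[str, str], ValueDefinition | None] = {}
    for node in iter_selectable_nodes(generated.trees):
        out.setdefault(node.term_code.key, node.value_definition)
    return out


def _leaf_keys(generated: GenerationResult) -> set[tuple[str, str]]:
    """Keys of selectable leaf criteria (first occurrence decides, matching
    the suite's per-leaf case construction)."""
    seen: dict[tuple[str, str], bool] = {}
    for node in iter_selectable_nodes(generated.trees):
        seen.setdefault(node.term_code.key, node.is_leaf)
    return {key for key, is_leaf in seen.items() if is_leaf}


def _selectable_codes(generated: GenerationResult) -> list[TermCode]:
    seen: dict[tuple[str, str], TermCode] = {}
    for node in iter_selectable_nodes(generated.trees):
        seen.setdefault(node.term_code.key, node.term_code)
    return [seen[k] for k in sorted(seen)]


def _build_param_paths(generated: GenerationResult
                       ) -> dict[tuple[str, str], str]:
    paths: dict[tuple[str, str], str] = {}
    for entry in generated.mapping:
        paths[(entry.resource_type, entry.term_code_search_parameter)] = (
            entry.term_code_fhir_path
        )
        if entry.value_search_parameter is not None:
            paths[(entry.resource_type, entry.value_search_parameter)] = (
                entry.value_fhir_path or ""
            )
        for fc in entry.fixed_criteria:
            paths[(entry.resource_type, fc.search_parameter)] = fc.fhir_path
    return paths


def gen_patients(
    spec: FixtureSpec,
    artifacts: ArtifactSet,
    generated: GenerationResult | None = None,
) -> ResourceStore:
    """Draw a synthetic population against the generated ontology.

    Each (patient, selectable criterion) pair is an independent Bernoulli
    draw at ``criterion_prevalence``; a hit materializes one conforming
    resource, including the profile's fixed-criterion fields and, for
    valued criteria, a concept drawn from the value set or a quantity drawn
    uniformly around the fixture threshold.  Condition criteria additionally
    produce occasional *unconfirmed* resources that must never match (the
    verification-status fixed criterion filters them).
    """
    if generated is None:
        generated = run_generation(artifacts)
    rng = random.Random(spec.seed + 1)
    value_defs = _value_definitions(generated)
    codes = _selectable_codes(generated)
    store = ResourceStore(
        param_paths=_build_param_paths(generated),
        quantity_range=spec.quantity_range,
    )
    lo, hi = spec.quantity_range
    for p in range(spec.n_patients):
        pid = f"P{p:04d}"
        store.patients.append(pid)
        for code in codes:
            entry = generated.mapping.lookup(code)
            vd = value_defs.get(code.key)
            if rng.random() < spec.criterion_prevalence:
                store.resources.append(_materialize(
                    entry, code, vd, pid, rng, lo, hi, confirmed=True,
                ))
            if (entry.resource_type == "Condition"
                    and rng.random() < spec.unconfirmed_rate):
                store.resources.append(_materialize(
                    entry, code, vd, pid, rng, lo, hi, confirmed=False,
                ))
    return store


def _materialize(
    entry: MappingEntry,
    code: TermCode,
    vd: ValueDefinition | None,
    pid: str,
    rng: random.Random,
    lo: float,
    hi: float,
    confirmed: bool,
) -> StoredResource:
    r = StoredResource(resource_type=entry.resource_type, patient=pid)
    r.coded[entry.term_code_fhir_path] = code
    for fc in entry.fixed_criteria:
        if fc.fhir_path == "Condition.verificationStatus" and not confirmed:
            r.coded[fc.fhir_path] = PROVISIONAL_TC
        else:
            r.coded[fc.fhir_path] = fc.values[0]
    if entry.value_search_parameter is not None and vd is not None:
        path = entry.value_fhir_path or ""
        if vd.kind == "concept":
            r.coded[path] = rng.choice(list(vd.selectable_concepts))
        else:
            value = round(rng.uniform(lo, hi), 1)
            r.quantities[path] = (value, vd.allowed_units[0])
    return r


# ---------------------------------------------------------------------------
# evaluators


_CMP = {
    "eq": lambda a, b: a == b,
    "ne": lambda a, b: a != b,
    "le": lambda a, b: a <= b,
    "ge": lambda a, b: a >= b,
    "lt": lambda a, b: a < b,
    "gt": lambda a, b: a > b,
}


def eval_filter(store: ResourceStore, f: SearchFilter) -> set[str]:
    """In-memory stand-in for a FHIR server executing one search filter.

    A resource matches iff every token parameter matches at least one of
    its tokens on (system, code), every quantity constraint holds under its
    comparator with exact unit equality, and all fixed parameters match.
    """
    out: set[str] = set()
    for r in store.resources_of(f.resource_type):
        ok = True
        for name, tokens in (*f.token_params, *f.fixed_params):
            path = store.param_paths.get((f.resource_type, name))
            if path is None:
                raise EvaluationError(
                    f"search parameter {name!r} of {f.resource_type} is not "
                    "in the store schema"
                )
            held = r.coded.get(path)
            if held is None or not any(tok == held for tok in tokens):
                ok = False
                break
        if ok:
            for name, constraints in f.quantity_params:
                path = store.param_paths.get((f.resource_type, name))
                if path is None:
                    raise EvaluationError(
                        f"search parameter {name!r} of {f.resource_type} is "
                        "not in the store schema"
                    )
                held_q = r.quantities.get(path)
                if held_q is None:
                    ok = False
                    break
                value, unit = held_q
                for c in constraints:
                    if unit != c.unit or not _CMP[c.comparator](value, c.value):
                        ok = False
                        break
                if not ok:
                    break
        if ok:
            out.add(r.patient)
    return out


def _tree_widen(roots: Sequence[TermTreeNode], tc: TermCode) -> set[TermCode]:
    """Self plus descendants of ``tc`` — written independently of the
    translator's widening so the oracle stays a separate route."""
    result: set[TermCode] = set()

    def subtree(node: TermTreeNode) -> set[TermCode]:
        acc = {node.term_code}
        for child in node.children:
            acc |= subtree(child)
        return acc

    stack = list(roots)
    while stack:
        node = stack.pop()
        if node.term_code == tc:
            result |= subtree(node)
        stack.extend(node.children)
    return result or {tc}


def _criterion_patients_bruteforce(
    store: ResourceStore,
    criterion: CriterionClause,
    tree: Sequence[TermTreeNode],
    mapping: CriterionMapping,
) -> set[str]:
    codes: set[TermCode] = set()
    for wire in criterion.term_codes:
        codes |= _tree_widen(tree, wire.to_term_code())
    out: set[str] = set()
    for code in codes:
        entry = mapping.lookup(code)
        for r in store.resources:
            if r.resource_type != entry.resource_type:
                continue
            if r.coded.get(entry.term_code_fhir_path) != code:
                continue
            if any(
                r.coded.get(fc.fhir_path) not in fc.values
                for fc in entry.fixed_criteria
            ):
                continue
            if not _value_matches_bruteforce(r, criterion, entry):
                continue
            out.add(r.patient)
    return out


def _value_matches_bruteforce(
    r: StoredResource, criterion: CriterionClause, entry: MappingEntry
) -> bool:
    vf = criterion.value_filter
    if vf is None:
        return True
    if entry.value_fhir_path is None:
        raise UnmappedCriterionError(
            f"criterion {entry.key.code} carries a value filter but maps "
            "no value attribute"
        )
    if isinstance(vf, ConceptFilter):
        held = r.coded.get(entry.value_fhir_path)
        wanted = {w.to_term_code() for w in vf.selected_concepts}
        return held is not None and held in wanted
    held_q = r.quantities.get(entry.value_fhir_path)
    if held_q is None:
        return False
    value, unit = held_q
    if isinstance(vf, QuantityComparatorFilter):
        return unit == vf.unit and _CMP[vf.comparator](value, vf.value)
    if isinstance(vf, QuantityRangeFilter):
        return unit == vf.unit and vf.min_value <= value <= vf.max_value
    raise UnmappedCriterionError(f"unknown value filter {vf!r}")


def eval_sq_bruteforce(
    store: ResourceStore,
    sq: StructuredQuery,
    tree: Sequence[TermTreeNode],
    mapping: CriterionMapping,
) -> set[str]:
    """Literal evaluation of ``inclusion (CNF) AND NOT exclusion (DNF)``,
    combining per-criterion patient sets with plain set algebra.

    Implemented independently of the query-plan machinery: this is the
    oracle the plan evaluation is checked against.
    """
    def crit(c: CriterionClause) -> set[str]:
        return _criterion_patients_bruteforce(store, c, tree, mapping)

    inclusion = set(store.patients)
    for clause in sq.inclusion:
        clause_set: set[str] = set()
        for criterion in clause:
            clause_set |= crit(criterion)
        inclusion &= clause_set
    exclusion: set[str] = set()
    for clause in sq.exclusion:
        clause_set = set(store.patients)
        for criterion in clause:
            clause_set &= crit(criterion)
        exclusion |= clause_set
    return inclusion - exclusion


# ---------------------------------------------------------------------------
# criterion suite, fault injection


@dataclass
class TestQueryCase:
    """One single-criterion SQ with its oracle-computed expected cohort."""

    criterion_key: tuple[str, str]
    sq: StructuredQuery
    expected_patient_ids: frozenset[str]


@dataclass
class SuiteReport:
    seed: int | None
    n_cases: int
    failures: list[tuple[tuple[str, str], str | None]]  # (key, fault class)

    @property
    def n_passed(self) -> int:
        return self.n_cases - len(self.failures)

    @property
    def ok(self) -> bool:
        return not self.failures


def _case_sq(code: TermCode, vd: ValueDefinition | None,
             quantity_range: tuple[float, float]) -> StructuredQuery:
    vf = None
    if vd is not None and vd.kind == "concept":
        vf = ConceptFilter(selected_concepts=[
            WireTermCode.from_term_code(tc) for tc in vd.selectable_concepts
        ])
    elif vd is not None and vd.kind == "quantity":
        lo, hi = quantity_range
        vf = QuantityRangeFilter(
            min_value=lo, max_value=hi, unit=vd.allowed_units[0],
        )
    clause = CriterionClause(
        term_codes=[WireTermCode.from_term_code(code)], value_filter=vf,
    )
    return StructuredQuery(inclusion=[[clause]])


def build_criterion_test_suite(
    generated: GenerationResult, store: ResourceStore,
) -> list[TestQueryCase]:
    """One single-criterion SQ per selectable leaf; valued criteria request
    the full value range so a conforming store matches every holder.
    Expected cohorts come exclusively from the brute-force evaluator."""
    value_defs = _value_definitions(generated)
    seen: set[tuple[str, str]] = set()
    cases: list[TestQueryCase] = []
    for node in iter_selectable_nodes(generated.trees):
        if not node.is_leaf or node.term_code.key in seen:
            continue
        seen.add(node.term_code.key)
        sq = _case_sq(node.term_code, value_defs.get(node.term_code.key),
                      store.quantity_range)
        expected = eval_sq_bruteforce(
            store, sq, generated.term_tree, generated.mapping
        )
        cases.append(TestQueryCase(
            criterion_key=node.term_code.key, sq=sq,
            expected_patient_ids=frozenset(expected),
        ))
    return cases


def run_suite(
    cases: Sequence[TestQueryCase],
    store: ResourceStore,
    generated: GenerationResult,
    fault_map: Mapping[tuple[str, str], str] | None = None,
    seed: int | None = None,
) -> SuiteReport:
    """Execute every case through the full translation path and compare with
    the expected cohort; failures are classified against ``fault_map``."""
    from .translate import sq_to_query_plan

    failures: list[tuple[tuple[str, str], str | None]] = []
    for case in cases:
        plan = sq_to_query_plan(case.sq, generated.mapping, generated.term_tree)
        actual = plan.evaluate(lambda f: eval_filter(store, f))
        if actual != case.expected_patient_ids:
            cls = (fault_map or {}).get(case.criterion_key)
            failures.append((case.criterion_key, cls))
    return SuiteReport(seed=seed, n_cases=len(cases), failures=failures)


def _pick(candidates: list[TermCode], rng: random.Random) -> TermCode | None:
    return rng.choice(candidates) if candidates else None


def inject_faults(
    store: ResourceStore,
    generated: GenerationResult,
    rng: random.Random,
    classes: Sequence[str] = FAULT_CLASSES,
) -> tuple[ResourceStore, dict[tuple[str, str], str]]:
    """Mutate a copy of the store to reproduce the four discrepancy classes
    between site data and the generated ontology.

    * ``version-drift`` — a criterion's resources are re-coded as a later
      terminology release would code them (code absent from the ontology);
    * ``unit-mismatch`` — a quantity criterion's resources switch to a unit
      dimension the ontology does not offer;
    * ``missing-system`` — resources switch to the equivalent concept of a
      code system that the single-CodeSystem rule removed from the UI;
    * ``subset-coding`` — resources use a postcoordinated (more specific)
      expression that expanded value sets do not contain.

    Returns the mutated store and a map from affected criterion key to
    fault class, against which suite failures are classified.
    """
    mutated = copy.deepcopy(store)
    value_defs = _value_definitions(generated)
    leaves = _leaf_keys(generated)
    fault_map: dict[tuple[str, str], str] = {}

    def held_codes() -> dict[tuple[str, str], list[StoredResource]]:
        by_code: dict[tuple[str, str], list[StoredResource]] = {}
        for r in mutated.resources:
            for entry in generated.mapping:
                if (r.resource_type == entry.resource_type
                        and r.coded.get(entry.term_code_fhir_path) == entry.key):
                    by_code.setdefault(entry.key.key, []).append(r)
        return by_code

    holders = held_codes()

    def candidates(pred) -> list[TermCode]:
        out = []
        for code in _selectable_codes(generated):
            if code.key in fault_map or code.key not in leaves:
                continue
            if not holders.get(code.key):
                continue
            if pred(code):
                out.append(code)
        return out

    def recode(code: TermCode, new: TermCode) -> None:
        entry = generated.mapping.lookup(code)
        for r in holders[code.key]:
            r.coded[entry.term_code_fhir_path] = new

    for cls in classes:
        if cls == "version-drift":
            code = _pick(candidates(
                lambda c: value_defs.get(c.key) is None
            ), rng)
            if code is not None:
                recode(code, TermCode(code.system, code.code + "-v103",
                                      code.display))
                fault_map[code.key] = cls
        elif cls == "unit-mismatch":
            code = _pick(candidates(
                lambda c: (vd := value_defs.get(c.key)) is not None
                and vd.kind == "quantity"
            ), rng)
            if code is not None:
                entry = generated.mapping.lookup(code)
                for r in holders[code.key]:
                    path = entry.value_fhir_path or ""
                    if path in r.quantities:
                        value, unit = r.quantities[path]
                        r.quantities[path] = (value, unit + "_alt")
                fault_map[code.key] = cls
        elif cls == "missing-system":
            code = _pick(candidates(lambda c: c.system == ICD10GM), rng)
            if code is not None:
                recode(code, TermCode(SNOMED, "413839001",
                                      "Chronic lung disease"))
                fault_map[code.key] = cls
        elif cls == "subset-coding":
            code = _pick(candidates(
                lambda c: value_defs.get(c.key) is None
            ), rng)
            if code is not None:
                recode(code, TermCode(code.system,
                                      code.code + ":postcoordinated",
                                      code.display))
                fault_map[code.key] = cls
        else:
            raise ValueError(f"unknown fault class {cls!r}")
    return mutated, fault_map


# ---------------------------------------------------------------------------
# random structured queries


def generate_random_sq(
    rng: random.Random,
    generated: GenerationResult,
    quantity_range: tuple[float, float] = (20.0, 80.0),
) -> StructuredQuery:
    """A random negation-free SQ over the generated ontology: 1–3 inclusion
    clauses of 1–3 criteria (CNF), 0–2 exclusion clauses (DNF), criteria
    drawn from all selectable codes (non-leaves exercise widening), value
    filters of every kind where the criterion supports one."""
    codes = _selectable_codes(generated)
    value_defs = _value_definitions(generated)
    lo, hi = quantity_range

    def one_criterion() -> CriterionClause:
        code = rng.choice(codes)
        term_codes = [WireTermCode.from_term_code(code)]
        if rng.random() < 0.15:
            term_codes.append(
                WireTermCode.from_term_code(rng.choice(codes))
            )
            return CriterionClause(term_codes=term_codes)
        vd = value_defs.get(code.key)
        vf = None
        if vd is not None and rng.random() < 0.6:
            if vd.kind == "concept":
                chosen = rng.sample(
                    list(vd.selectable_concepts),
                    rng.randint(1, len(vd.selectable_concepts)),
                )
                vf = ConceptFilter(selected_concepts=[
                    WireTermCode.from_term_code(tc) for tc in chosen
                ])
            else:
                unit = vd.allowed_units[0]
                if rng.random() < 0.5:
                    vf = QuantityComparatorFilter(
                        comparator=rng.choice(
                            ["eq", "ne", "le", "ge", "lt", "gt"]
                        ),
                        value=round(rng.uniform(lo, hi), 1),
                        unit=unit,
                    )
                else:
                    a = round(rng.uniform(lo, hi), 1)
                    b = round(rng.uniform(lo, hi), 1)
                    vf = QuantityRangeFilter(
                        min_value=min(a, b), max_value=max(a, b), unit=unit,
                    )
        return CriterionClause(term_codes=term_codes, value_filter=vf)

    inclusion = [
        [one_criterion() for _ in range(rng.randint(1, 3))]
        for _ in range(rng.randint(1, 3))
    ]
    n_exc = rng.choice([0, 0, 1, 1, 2])
    exclusion = [
        [one_criterion() for _ in range(rng.randint(1, 2))]
        for _ in range(n_exc)
    ]
    return StructuredQuery(inclusion=inclusion, exclusion=exclusion)
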