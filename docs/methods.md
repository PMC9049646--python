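# Methods

This note documents the models and procedures implemented in `feasquery`,
the parameters that matter, the synthetic data the tests run on, and the
design choices made where more than one reasonable design existed.

## The generation model

The generator consumes four kinds of FHIR R4 conformance artifacts: a
LogicalModel whose first-level elements are UI categories and whose
second-level elements name criteria (each criterion name identifies a
profile), `StructureDefinition` profiles, `ValueSet`s, and `CodeSystem`s.
Snapshot element views are preferred, differentials accepted, so inputs
need no snapshot-generation step. Choice-type paths (`value[x]`) are
normalized at parse time to the concrete typed path when the profile
constrains a single type.

A criterion is a `(system, code)` pair; display text and system version are
excluded from identity because terminology releases drift while the pair
stays stable. Per profile, a *handler* decides which element specifies the
criteria and which, if any, specifies a value:

| handler | criteria attribute | value | value kind |
|---|---|---|---|
| Condition | `Condition.code` | — | none |
| Observation (concept) | `Observation.code` | `value[x]` = CodeableConcept | concept |
| Observation (quantity) | `Observation.code` | `value[x]` = Quantity | quantity |
| Procedure | `Procedure.code` | — | none |
| MedicationStatement | `medication[x]` | — | none |
| Immunization | `Immunization.vaccineCode` | — | none |
| DiagnosticReport | `DiagnosticReport.code` | coded conclusion | concept-like |
| Specimen | `Specimen.type` | — | none |

Observation profiles are disambiguated concept-vs-quantity by the
constrained type of `value[x]`. Seven corner-case handlers, consulted
before the defaults and matched by profile name or canonical URL, cover
profiles the per-type defaults cannot: an integer-valued score read from
`value[integer]`; a component-held concept (history of travel); two
component-held quantities (systolic and diastolic blood pressure, counted
separately because each reads a different component slice); a condition
whose severity is settable as a value; and two extensions (ethnic group,
age) that need custom search parameters and paths. A deny list excludes
the date-of-birth criterion outright: releasing birth dates alongside
cohort counts would be a re-identification risk.

Criteria sets come from expanding the binding of the criteria-specifying
attribute. Expansion is local by default (sites and CI run no terminology
server); a `ValueSet/$expand` client with the identical contract can be
dropped in. Where an expansion spans several code systems, only the
highest-preference system present is kept — fixed order ICD-10-GM,
SNOMED CT, LOINC, ATC, ICD-10-GM first for its broad clinical adoption,
the rest ordered by prevalence in COVID-19-era profile sets. Overlapping
concepts (sleep apnea exists in both ICD-10-GM and SNOMED CT) therefore
appear once. If no preferred system is present the expansion is kept whole
with a warning rather than silently emptied.

The expansion is shaped along the is-a relations of its code systems into
a *subsumption forest*: the transitive reduction (via `networkx`) of the
is-a closure restricted to the expansion members. Two policies matter:

- a member whose parent is absent from the expansion attaches to its
  nearest expanded ancestor (or becomes a root), preserving subsumption
  semantics for query widening;
- multi-parent concepts keep all their parents in the forest and are
  duplicated under each parent when rendered into the (strictly tree-
  shaped) UI and terminology-tree outputs — duplication preserves
  findability.

Sibling order is lexicographic by display then code, making all outputs
byte-deterministic. Each criterion's forest is appended below a
non-selectable group node named after the profile; every concept node is
selectable and carries the profile's value definition (concept choices, or
a unit plus the comparator set `{eq, ne, le, ge, lt, gt}`). Units are
taken verbatim from the profile (the fixed `.code` child of the quantity
element); there is no unit conversion anywhere, and integer scores use the
UCUM dimensionless unit `1`.

## Mapping and terminology tree

The UI profiles carry no FHIR-model or query-language information, and the
Structured Query carries no hierarchy; two artifacts reintroduce that at
translation time. The *mapping* holds one entry per selectable code:
ResourceType, search parameter and path of the criterion code, of the
optional value, and the *fixed criteria* silently appended to every query
(Condition entries pin `verification-status` to `confirmed` by default,
configurable per profile; component corner cases pin the component code).
A code emitted by two profiles is a hard generation error — ambiguous
translation is worse than failed generation. Paths without a standard R4
search parameter (extensions, component slices, `value[integer]`) resolve
through a shipped custom-parameter registry that can also be emitted as
FHIR `SearchParameter` resources for server registration. The
*terminology tree* is the structural projection of the UI trees to nodes
of exactly two properties, code and children.

## The Structured Query and its translation

The SQ wire format (version tag `feasquery-sq-1`, a local format defined
by this package and shipped as JSON Schema) has inclusion criteria in CNF
and exclusion criteria in DNF, both negation-free by construction — the
schema has no negation field, so the only negation in the algebra is the
single AND-NOT combining the two parts. Empty inclusion is invalid (a
feasibility query must include someone); empty exclusion excludes nobody.
A criterion names one or more alternative codes and at most one value
filter (concept, quantity comparator, or quantity range).

Translation widens every criterion code to itself plus its descendants in
the terminology tree (client-side, since sites lack the terminology server
a `:below` modifier would need; codes absent from the tree pass through
with a warning). The widened codes become comma-joined OR tokens of one
search parameter; codes spanning incompatible mapping entries split into
several filters joined by UNION. The full plan is
`(INTERSECT of per-clause UNIONs) DIFFERENCE (UNION of per-clause
INTERSECTs)`, with DIFFERENCE appearing exactly once, at the root, iff the
exclusion is non-empty. Patient identity for the set algebra is the
resource's subject reference; Patient-typed criteria use the resource ID
itself. Quantity constraints render as comparator-prefixed values
(`gt70|http://unitsofmeasure.org|kg`, `eq` unprefixed); ranges render as a
`ge`/`le` pair on the same parameter; units compare by exact code. Request
strings are deterministic: criterion parameter first, then value, then
fixed parameters, each group sorted, reserved characters percent-encoded.

The CQL emitter produces one define per criterion (retrieve filtered by
the inlined expanded code list, fixed criteria and value filters as
where-clauses; no external ValueSet references, keeping the library
self-contained) and a population define combining them with `and`/`or`/
`not` exactly per the SQ formula. The emitter is structural: its output is
checked for cross-emitter consistency (each define's code list equals the
corresponding FHIR Search token set) but is not executed against a CQL
engine, a known limitation.

## Synthetic data and what the tests show

`FixtureSpec` defaults define the study conditions: the full roster of
Table-style ResourceType profiles and all corner cases spread over 4
categories (plus synthetic Condition criteria drawn from 2 random code
systems of 24 codes, filling 5 criteria per category), 200 patients, and
20% criterion prevalence, so single-criterion cohorts average ~40
patients. One roster ValueSet deliberately mixes ICD-10-GM and SNOMED CT
codes for the same concepts to exercise the preference rule. Quantity
values are drawn uniformly on a ±30 band around a threshold of 50 (one
decimal), so every comparator sees matches, non-matches, and boundary
ties; Condition criteria also generate occasional *unconfirmed* resources
that the fixed criterion must filter out. Patient resources are flat
records keyed by dotted FHIR path — exactly the fields the mapped queries
touch.

Oracles are independent routes: the brute-force SQ evaluator combines
per-criterion patient sets by the literal formula and shares no code with
the plan machinery; forest construction is checked against naive
BFS-closure reduction written in the tests. The acceptance checks run
1000 random SQs (nesting depths 1–3, all filter kinds, non-leaf widening)
against 200 patients and random DAG code systems up to 200 nodes; both
finish in well under a minute on one CPU, so no scaling-down tricks are
needed. The fault injector recodes a leaf criterion's resources per
discrepancy class (a later-release code, an off-dimension unit, the
equivalent code of the non-displayed system, a postcoordinated variant);
the suite must fail exactly those criteria and classify each failure.

Passing these tests shows the pipeline is internally consistent and its
set semantics exact under the modeled feature set. It does not show
robustness to real GECCO artifacts in full fidelity: real
StructureDefinitions carry slicing, cardinality and extension structure
far beyond the modeled subset, real terminologies are orders of magnitude
larger, real instance data is not flat, and free-text conclusions are only
approximated by coded conclusions (the value algebra has no text kind).
Unit conversion, SNOMED postcoordination resolution, and cross-system
concept mapping are out of scope, mirroring the documented limitations of
the production approach this package models.

## Numerical and degenerate-input choices

- All artifact I/O is UTF-8; JSON outputs use two-space indentation and
  fixed key order, so identical inputs give byte-identical outputs.
- Quantity comparisons are exact float comparisons on values rounded to
  one decimal in fixtures; no tolerance is applied (FHIR quantity search
  semantics at this granularity are exact).
- Empty expansions after code-system filtering yield an empty criterion
  with a warning, not an error; unresolved criterion names and
  per-criterion generation failures are collected into the generation
  report rather than aborting the run.
- Cycles in is-a relations are rejected at parse time with one offending
  cycle listed; self-edges are cycles.
- The seed is the single source of randomness everywhere (generation,
  population, fault choice, random queries); suite reports record it.
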