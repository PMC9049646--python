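# feasquery

Feasibility queries — "how many patients at the participating hospitals
match these criteria?" — are the first step of most clinical studies. In a
federated network whose sites store harmonized data on FHIR servers (for
example the German COVID-19 GECCO dataset, 83 data elements profiled in
FHIR), researchers cannot be expected to write FHIR Search or CQL by hand.
`feasquery` implements the machinery that makes a visual query builder
possible on top of raw FHIR profiles:

1. **Ontology generation.** From a LogicalModel (categories and criterion
   names), FHIR `StructureDefinition` profiles, and terminology expansions,
   it generates the *UI profiles*: a hierarchical tree of selectable
   criteria, each identified by a `(system, code)` pair, with an optional
   value definition (a concept choice or a quantity with unit and
   comparators). Profiles are handled per ResourceType (the
   criteria-specifying attribute is `Condition.code`,
   `Immunization.vaccineCode`, `Specimen.type`, …) with an explicit
   corner-case registry for profiles that deviate — integer-valued scores,
   component slices such as blood pressure, extensions such as age and
   ethnic group. Where ValueSets span several code systems the expansion
   is reduced to one (ICD-10-GM preferred) so overlapping concepts appear
   once.
2. **Mapping and terminology tree.** Alongside the UI tree it generates a
   per-criterion *mapping* (ResourceType, search parameters, FHIR paths,
   fixed criteria such as `verification-status=confirmed`, custom
   `SearchParameter` resources for paths without a standard one) and a
   *terminology tree* (the ontology reduced to codes and children) used to
   widen non-leaf criteria to their descendants at translation time.
3. **Query translation.** The intermediate *Structured Query* format
   (inclusion criteria in CNF, exclusion criteria in DNF, both
   negation-free, combined as `inclusion AND NOT exclusion`) is translated
   into a set-algebra plan over FHIR Search requests —
   `(∩ of ∪) ∖ (∪ of ∩)` with per-criterion token/quantity parameters —
   and into a self-contained CQL library.
4. **Reference evaluation.** A synthetic-fixture module generates
   conformance artifacts and patient-level resources, and brute-force
   evaluators recompute every cohort independently of the plan machinery,
   including a fault injector reproducing four realistic data-discrepancy
   classes (version drift, unit mismatch, missing-system codes, subset
   coding).

## Worked example

```python
from feasquery.fixtures import FixtureSpec, gen_artifacts
from feasquery.pipeline import run_generation
from feasquery.sq import parse_sq, SQ_VERSION
from feasquery.translate import render_plan_requests, sq_to_query_plan

generated = run_generation(gen_artifacts(FixtureSpec(seed=1)))
sq = parse_sq({
    "version": SQ_VERSION,
    "inclusion": [[{"termCodes": [
        {"system": "http://fhir.de/CodeSystem/dimdi/icd-10-gm", "code": "J44"}
    ]}]],
    "exclusion": [],
})
plan = sq_to_query_plan(sq, generated.mapping, generated.term_tree)
print(render_plan_requests(plan)[0])
```

prints

```
Condition?code=http%3A%2F%2Ffhir.de%2FCodeSystem%2Fdimdi%2Ficd-10-gm%7CJ44,http%3A%2F%2Ffhir.de%2FCodeSystem%2Fdimdi%2Ficd-10-gm%7CJ44.0,http%3A%2F%2Ffhir.de%2FCodeSystem%2Fdimdi%2Ficd-10-gm%7CJ44.1&verification-status=http%3A%2F%2Fterminology.hl7.org%2FCodeSystem%2Fcondition-ver-status%7Cconfirmed
```

The non-leaf COPD code `J44` was widened through the terminology tree to
its subcodes `J44.0` and `J44.1` (comma-joined OR tokens of the `code`
parameter), and the mapping appended the fixed criterion restricting the
search to confirmed diagnoses. Longer narrative walks live in `examples/`:

- `examples/generate_ontology.py` — artifact set to category trees and
  mapping entries;
- `examples/translate_query.py` — an SQ with quantity filter and exclusion
  rendered to FHIR Search and CQL;
- `examples/evaluate_against_oracle.py` — criterion suite, random-query
  oracle comparison, and fault injection (prints `61/61 passed`,
  `0 plan/oracle mismatches`, and four classified failures).

There is also a thin CLI over the same functions:

```sh
feasquery fixtures --seed 1 --out artifacts/
feasquery generate --input-dir artifacts/ --output-dir generated/
feasquery translate --sq query.json --mapping generated/mapping.json \
    --tree generated/terminology_tree.json --to fhir-search
feasquery evaluate --seed 1
```

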