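"""Translate a Structured Query into FHIR Search requests and CQL.

The query asks for patients with a chronic obstructive pulmonary disease
(non-leaf ICD-10-GM code J44, widened to its subcodes via the terminology
tree) weighing more than 70 kg, excluding vaccinated patients.
"""

from feasquery.fixtures import FixtureSpec, gen_artifacts
from feasquery.pipeline import run_generation
from feasquery.sq import parse_sq, SQ_VERSION
from feasquery.translate import render_plan_requests, sq_to_cql, sq_to_query_plan

generated = run_generation(gen_artifacts(FixtureSpec(seed=1)))

sq = parse_sq({
    "version": SQ_VERSION,
    "inclusion": [
        [{"termCodes": [{"system": "http://fhir.de/CodeSystem/dimdi/icd-10-gm",
                         "code": "J44"}]}],
        [{"termCodes": [{"system": "http://loinc.org", "code": "29463-7"}],
          "valueFilter": {"kind": "quantity-comparator",
                          "comparator": "gt", "value": 70, "unit": "kg"}}],
    ],
    "exclusion": [
        [{"termCodes": [{"system": "http://snomed.info/sct",
                         "code": "787859002"}]}],
    ],
})

plan = sq_to_query_plan(sq, generated.mapping, generated.term_tree)
print("FHIR Search requests (one per plan leaf):")
for request in render_plan_requests(plan):
    print(" ", request)
# The first request ORs J44 with its descendants J44.0 and J44.1 as comma
# tokens and pins verification-status=confirmed; the second carries the
# prefixed quantity gt70|...|kg; the third widens the vaccine product code.

print("\nplan shape: INTERSECT of inclusion UNIONs minus the exclusion")
print(" ", plan.root.op, "with", len(plan.root.children), "operands")

print("\nCQL library:")
print(sq_to_cql(sq, generated.mapping, generated.term_tree))
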