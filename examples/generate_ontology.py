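"""Generate a feasibility-query ontology from conformance artifacts.

Builds a synthetic GECCO-like artifact set (LogicalModel, profiles,
ValueSets, CodeSystems), runs the generator, and prints what came out:
the category trees with their criteria hierarchies, the mapping size, and
an excerpt of one mapping entry.
"""

import json

from feasquery.fixtures import FixtureSpec, gen_artifacts
from feasquery.pipeline import run_generation
from feasquery.artifacts import TermCode
from feasquery.systems import ICD10GM

spec = FixtureSpec(seed=1)
artifacts = gen_artifacts(spec)
generated = run_generation(artifacts)

print("categories and criteria")
for tree in generated.trees:
    names = [root.display for root in tree.roots]
    print(f"  {tree.category_name}: {', '.join(names)}")

# the chronic-lung-disease group carries the ICD-10-GM hierarchy below it:
# J40-J47 with J44/J45/J47 children, leaf codes below those.  The SNOMED
# duplicates from the mixed ValueSet were removed by the preference rule.
cld = next(
    root for tree in generated.trees for root in tree.roots
    if root.display == "ChronicLungDisease"
)


def show(node, indent="  "):
    mark = "*" if node.selectable else " "
    print(f"{indent}{mark} {node.term_code.code}  {node.display}")
    for child in node.children:
        show(child, indent + "  ")


print("\nChronicLungDisease criteria tree (* = selectable):")
for child in cld.children:
    show(child)

print(f"\nmapping entries: {len(generated.mapping)}")
entry = generated.mapping.lookup(TermCode(ICD10GM, "J44"))
print("mapping entry for J44 (COPD):")
print(json.dumps(entry.to_json(), indent=2))
# searchParameter "code" locates the criterion; the fixed criterion pins
# verificationStatus to "confirmed" so only verified diagnoses count.
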