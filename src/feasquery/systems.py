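"""Canonical terminology-system URIs used across the package."""

ICD10GM = "http://fhir.de/CodeSystem/dimdi/icd-10-gm"
SNOMED = "http://snomed.info/sct"
LOINC = "http://loinc.org"
ATC = "http://fhir.de/CodeSystem/dimdi/atc"
UCUM = "http://unitsofmeasure.org"
CONDITION_VER_STATUS = "http://terminology.hl7.org/CodeSystem/condition-ver-status"

#: Synthetic system identifying non-selectable criterion-group nodes in the
#: UI tree (one per profile; their codes never occur in queries).
CRITERION_GROUP = "http://feasquery.local/criterion-group"

#: Single-CodeSystem display preference: when an expansion spans several
#: systems, only the highest-ranked system present is shown, ICD-10-GM
#: first for its broad adoption in clinics.
DEFAULT_PREFERENCE = (ICD10GM, SNOMED, LOINC, ATC)
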