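{
  "description": "Standard FHIR R4 search parameters for the element paths the criteria handlers read.",
  "parameters": [
    {"resourceType": "Condition", "path": "Condition.code", "name": "code"},
    {"resourceType": "Condition", "path": "Condition.severity", "name": "severity"},
    {"resourceType": "Condition", "path": "Condition.verificationStatus", "name": "verification-status"},
    {"resourceType": "Observation", "path": "Observation.code", "name": "code"},
    {"resourceType": "Observation", "path": "Observation.valueCodeableConcept", "name": "value-concept"},
    {"resourceType": "Observation", "path": "Observation.valueQuantity", "name": "value-quantity"},
    {"resourceType": "Procedure", "path": "Procedure.code", "name": "code"},
    {"resourceType": "MedicationStatement", "path": "MedicationStatement.medicationCodeableConcept", "name": "code"},
    {"resourceType": "Immunization", "path": "Immunization.vaccineCode", "name": "vaccine-code"},
    {"resourceType": "DiagnosticReport", "path": "DiagnosticReport.code", "name": "code"},
    {"resourceType": "Specimen", "path": "Specimen.type", "name": "type"}
  ]
}
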