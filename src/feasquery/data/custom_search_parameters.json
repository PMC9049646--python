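{
  "description": "Custom search parameters for paths without a standard R4 parameter: extensions, component slices, and value[integer]. Emitted as FHIR SearchParameter resources for server registration.",
  "parameters": [
    {"resourceType": "Observation", "path": "Observation.valueInteger", "name": "value-integer", "type": "number"},
    {"resourceType": "Observation", "path": "Observation.component:travel.code", "name": "travel-component-code", "type": "token"},
    {"resourceType": "Observation", "path": "Observation.component:travel.valueCodeableConcept", "name": "travel-value-concept", "type": "token"},
    {"resourceType": "Observation", "path": "Observation.component:systolic.code", "name": "systolic-component-code", "type": "token"},
    {"resourceType": "Observation", "path": "Observation.component:systolic.valueQuantity", "name": "systolic-value-quantity", "type": "quantity"},
    {"resourceType": "Observation", "path": "Observation.component:diastolic.code", "name": "diastolic-component-code", "type": "token"},
    {"resourceType": "Observation", "path": "Observation.component:diastolic.valueQuantity", "name": "diastolic-value-quantity", "type": "quantity"},
    {"resourceType": "DiagnosticReport", "path": "DiagnosticReport.conclusionCode", "name": "conclusion", "type": "token"},
    {"resourceType": "Patient", "path": "Patient.extension:ethnicGroup.valueCoding", "name": "ethnic-group", "type": "token"},
    {"resourceType": "Patient", "path": "Patient.extension:age.code", "name": "age-code", "type": "token"},
    {"resourceType": "Patient", "path": "Patient.extension:age.valueQuantity", "name": "age", "type": "quantity"}
  ]
}
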