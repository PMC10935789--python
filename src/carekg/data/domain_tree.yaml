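# Question-class taxonomy (domain tree). Leaves are listed in priority
# order: the first leaf whose trigger phrases and required entity label are
# both satisfied wins. Trigger phrases are matched case-insensitively on
# word boundaries. `pattern` drives the in-memory triple match; `cypher`
# drives the emitted graph-query string.
leaves:
  - id: disease_food
    triggers: [eat, food, foods, diet, dietary]
    entity_label: disease
    pattern: {source_label: disease, categories: [prevention, diet_information], target_label: diet}
    cypher: {source: Disease, rels: [PREVENTS, DIET_INFORMATION], target: Diet}
    answer: "For {entity}, the following foods are suitable: {items}."

  - id: disease_cause
    triggers: [why, reason, reasons, cause, causes, caused]
    entity_label: disease
    pattern: {source_label: disease, categories: [initiation], target_label: null}
    cypher: {source: Disease, rels: [INITIATION], target: null}
    answer: "Factors associated with developing {entity}: {items}."

  - id: disease_prevention
    triggers: [prevent, prevention, avoid, reduce the risk]
    entity_label: disease
    pattern: {source_label: disease, categories: [prevention], target_label: null}
    cypher: {source: Disease, rels: [PREVENTS], target: null}
    answer: "To help prevent {entity}: {items}."

  - id: disease_examination
    triggers: [examination, examinations, check, checked, test, tests, screening]
    entity_label: disease
    pattern: {source_label: disease, categories: [examination], target_label: examination}
    cypher: {source: Disease, rels: [EXAMINATION], target: Examination}
    answer: "Recommended examinations for {entity}: {items}."

  - id: disease_symptom
    triggers: [symptom, symptoms, manifestation, manifestations, signs, feel]
    entity_label: disease
    pattern: {source_label: disease, categories: [diagnosis], target_label: symptom}
    cypher: {source: Disease, rels: [DIAGNOSIS], target: Symptom}
    answer: "{entity} may present with: {items}."

  - id: disease_drug
    triggers: [drug, drugs, medicine, medicines, medication, medications, take, treat, treats, treatment]
    entity_label: disease
    pattern: {source_label: disease, categories: [treatment], target_label: medication}
    cypher: {source: Disease, rels: [TREATS], target: Medication}
    answer: "Medications used to treat {entity}: {items}."

  - id: drug_disease
    triggers: [treat, treats, used for, cure, cures, indication, for what]
    entity_label: medication
    pattern: {source_label: medication, categories: [treatment], target_label: disease}
    cypher: {source: Medication, rels: [TREATS], target: Disease}
    answer: "{entity} is used to treat: {items}."

  - id: symptom_disease
    triggers: [disease, diseases, sign of, indicate, indicates, suggest, suggests]
    entity_label: symptom
    pattern: {source_label: symptom, categories: [diagnosis], target_label: disease}
    cypher: {source: Symptom, rels: [DIAGNOSIS], target: Disease}
    answer: "{entity} may be associated with: {items}."
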