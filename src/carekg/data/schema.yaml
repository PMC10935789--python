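# Concept layer of the elderly chronic-disease care knowledge graph.
# 31 node labels and 9 relation categories; edge_patterns whitelists which
# (source-label, target-label, category) triples may exist.

labels:
  - name
  - sex
  - age
  - type
  - subsidy
  - income
  - expenditure
  - excretion
  - collateral_chronic_history
  - direct_chronic_history
  - sleep
  - diet
  - sport
  - physical_condition
  - hobby
  - psychology
  - psychological_factor
  - marriage
  - spouse
  - child
  - child_type
  - caregiver
  - physical_index
  - living_environment
  - disease
  - medication
  - symptom
  - examination
  - smart_phone
  - smart_device
  - social

categories:
  - basic_information
  - physical_information
  - diet_information
  - initiation
  - prevention
  - treatment
  - diagnosis
  - complication
  - examination

edge_patterns:
  # elder demographics, history, possessions and relations
  - [name, sex, basic_information]
  - [name, age, basic_information]
  - [name, type, basic_information]
  - [name, subsidy, basic_information]
  - [name, income, basic_information]
  - [name, expenditure, basic_information]
  - [name, marriage, basic_information]
  - [name, spouse, basic_information]
  - [name, child, basic_information]
  - [name, caregiver, basic_information]
  - [name, hobby, basic_information]
  - [name, social, basic_information]
  - [name, living_environment, basic_information]
  - [name, smart_phone, basic_information]
  - [name, smart_device, basic_information]
  - [name, disease, basic_information]
  - [name, medication, basic_information]
  - [name, direct_chronic_history, basic_information]
  - [name, collateral_chronic_history, basic_information]
  - [name, examination, basic_information]
  - [child, child_type, basic_information]
  - [name, child_type, basic_information]
  # elder body state and behaviour
  - [name, sleep, physical_information]
  - [name, sport, physical_information]
  - [name, psychology, physical_information]
  - [name, physical_condition, physical_information]
  - [name, physical_index, physical_information]
  - [name, symptom, physical_information]
  - [name, excretion, physical_information]
  - [psychology, psychological_factor, physical_information]
  - [name, psychological_factor, physical_information]
  # elder dietary habits
  - [name, diet, diet_information]
  - [disease, diet, diet_information]
  # aetiology: lifestyle / body state raises disease risk
  - [sleep, disease, initiation]
  - [diet, disease, initiation]
  - [sport, disease, initiation]
  - [psychology, disease, initiation]
  - [psychological_factor, disease, initiation]
  - [physical_index, disease, initiation]
  - [physical_condition, disease, initiation]
  - [excretion, disease, initiation]
  - [disease, disease, initiation]
  # prevention
  - [diet, disease, prevention]
  - [sport, disease, prevention]
  - [hobby, disease, prevention]
  - [sleep, disease, prevention]
  # curated medical knowledge
  - [medication, disease, treatment]
  - [physical_index, disease, diagnosis]
  - [name, disease, diagnosis]
  - [symptom, disease, diagnosis]
  - [disease, symptom, diagnosis]
  - [disease, disease, complication]
  - [disease, examination, examination]

label_attributes:
  name: [height_m, weight_kg, recorded_at]
  medication: [dose, frequency]
  disease: [description]
  physical_index: [family, degree]
  examination: [interval_months]
  diet: [note]
  sleep: [note]
  symptom: [note]
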