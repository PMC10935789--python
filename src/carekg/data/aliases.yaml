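# Surface-form aliases resolving to canonical graph concepts.
aliases:
  high blood pressure: [disease, hypertension]
  high blood sugar: [disease, diabetes]
  sugar diabetes: [disease, diabetes]
  high blood fat: [disease, hyperlipidemia]
  high cholesterol: [disease, hyperlipidemia]
  heart disease: [disease, coronary heart disease]
  dementia: [disease, "alzheimer's disease"]
  alzheimers: [disease, "alzheimer's disease"]
  stroke: [disease, cerebrovascular disease]
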