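# Declarative registration-consistency rules.
#
# A rule walks a chain of hops from the elder node (undirected, label- and
# category-constrained) and fires when the chain exists but the elder lacks
# a direct edge (in any of absent_categories) to the chain's end node.
rules:
  - id: medication-disease-consistency
    kind: registration
    hops:
      - {category: basic_information, label: medication}
      - {category: treatment, label: disease}
    absent_categories: [basic_information, diagnosis]
    severity: warning
    message: "{elder} is taking {via}, which treats {end}, but {end} is not registered; please confirm medication and disease status."
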