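drug_a,drug_b
aspirin,warfarin
nifedipine,metoprolol
metformin,glibenclamide
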