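# Sentence templates used by the care-report recommendation subsections.
prevention_diet: "Elderly people at risk of {disease} should pay attention to the diet; recommended: {items}."
prevention_habit: "To help prevent {disease}, the following habits are recommended: {items}."
examination: "For {disease}, the following examinations should be scheduled regularly: {items}."
measurement: "No recent {measure} readings are on record; {measure} should be measured regularly for elders with {disease}."
caveat: "{disease} may require special attention in daily care; caregivers should observe the elder's condition and course of {disease}."
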