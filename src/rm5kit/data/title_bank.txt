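Mental state
Global state
Adverse events
Leaving the study early
Service utilisation: hospital admission
Quality of life
Social functioning
Death
Weight gain
Extrapyramidal symptoms
Relapse
Clinically important change in mental state
Average endpoint score (BPRS)
Average change score (PANSS)
Compliance with medication
Employment status
Aggressive behaviour
Anxiety symptoms
Depression symptoms
Cognitive functioning
Sleep quality
Sedation
Dry mouth
Constipation
Dizziness
Seizures
Tardive dyskinesia
Akathisia
Need for additional medication
Satisfaction with care
Carer burden
Economic outcomes: direct costs
Readmission within one year
Time in hospital
General functioning (GAF)
Insight
Suicide attempts
Self-harm
Physical health: blood pressure
Prolactin level
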