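original_code,group_label
Office,Ambulatory
Home,Ambulatory
UrgentCare,Emergent
Emergency,Emergent
Ambulance,Emergent
OutpatientHospital,Outpatient
IndependentLab,Outpatient
InpatientHospital,Inpatient
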