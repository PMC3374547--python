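original_code,group_label
Internal,PrimaryCare
GeneralPractice,PrimaryCare
Pediatrics,PrimaryCare
Surgery,Procedural
Anesthesiology,Procedural
Emergency,Emergency
DiagnosticImaging,Diagnostics
Laboratory,Diagnostics
Obstetrics,Other
Other,Other
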