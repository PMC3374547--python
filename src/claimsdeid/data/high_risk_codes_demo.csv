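code_system,pattern
icd9,042
icd9,V08
icd9,635
cpt,59840
cpt,59841
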