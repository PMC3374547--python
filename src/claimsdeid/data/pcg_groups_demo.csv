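original_code,group_label
250,DIABETES
401,HYPERTENSION
402,HYPERTENSION
428,CHF
414,IHD
410,AMI
486,PNEUMONIA
491,COPD
493,ASTHMA
540,ACUTEGI
571,LIVERDZ
585,RENAL
162,CANCER
174,CANCER
153,CANCER
296,MOOD
311,MOOD
331,NEURO
042,HIV
V08,HIV
635,PREGNANCY
715,ARTHROPATHY
724,ARTHROPATHY
780,MISC
V70,PREVENTIVE
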