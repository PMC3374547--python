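icd9_prefix,weight
250,1
410,1
414,1
428,1
491,1
493,1
331,1
585,2
162,2
174,2
153,2
571,3
042,6
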