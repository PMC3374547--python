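original_code,group_label
99213,EM
99214,EM
99203,EM
99204,EM
99285,EM
99221,EM
71020,Radiology
71250,Radiology
74150,Radiology
80053,Laboratory
80061,Laboratory
85025,Laboratory
36415,Laboratory
93000,Medicine
97110,Medicine
90471,Medicine
45378,Surgery
27447,Surgery
59400,Surgery
66984,Surgery
59840,Surgery
59841,Surgery
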