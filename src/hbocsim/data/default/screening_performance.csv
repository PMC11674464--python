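modality,age_from,age_to,sensitivity,specificity
mammography,0,39,0.62,0.92
mammography,40,49,0.7,0.95
mammography,50,59,0.8,0.96
mammography,60,100,0.85,0.96
MRI,0,100,0.9,0.9
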