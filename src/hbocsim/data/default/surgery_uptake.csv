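surgery,gene,age_from,age_to,annual_probability
BRRM,BRCA1,18,39,0.04
BRRM,BRCA1,40,49,0.025
BRRM,BRCA1,50,69,0.008
BRRM,BRCA2,18,39,0.04
BRRM,BRCA2,40,49,0.025
BRRM,BRCA2,50,69,0.008
BRRM,PALB2,18,39,0.04
BRRM,PALB2,40,49,0.025
BRRM,PALB2,50,69,0.008
BRRM,ATM,18,39,0.02
BRRM,ATM,40,49,0.0125
BRRM,ATM,50,69,0.004
BRRM,CHEK2_1100delC,18,39,0.02
BRRM,CHEK2_1100delC,40,49,0.0125
BRRM,CHEK2_1100delC,50,69,0.004
RRSO,BRCA1,35,44,0.1
RRSO,BRCA1,45,54,0.13
RRSO,BRCA1,55,74,0.06
RRSO,BRCA2,40,49,0.09
RRSO,BRCA2,50,59,0.11
RRSO,BRCA2,60,74,0.05
RRSO,PALB2,50,59,0.1
RRSO,PALB2,60,74,0.05
RRSO,RAD51C,45,59,0.1
RRSO,RAD51C,60,74,0.05
RRSO,RAD51D,45,59,0.1
RRSO,RAD51D,60,74,0.05
RRSO,BRIP1,60,74,0.08
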