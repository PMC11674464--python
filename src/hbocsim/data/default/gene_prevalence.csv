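gene,prevalence
BRCA1,0.002
BRCA2,0.003
PALB2,0.002
CHEK2_1100delC,0.003
ATM,0.0035
RAD51C,0.0007
RAD51D,0.0005
BRIP1,0.001
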