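degree,age_band,time_band,probability
1,<18,<1,0.0
1,<18,1-3,0.0
1,<18,>3,0.0
1,18-29,<1,0.259
1,18-29,1-3,0.098
1,18-29,>3,0.071
1,30-49,<1,0.286
1,30-49,1-3,0.098
1,30-49,>3,0.022
1,50-59,<1,0.146
1,50-59,1-3,0.033
1,50-59,>3,0.01
1,60+,<1,0.099
1,60+,1-3,0.014
1,60+,>3,0.007
2,<18,<1,0.0
2,<18,1-3,0.0
2,<18,>3,0.0
2,18-29,<1,0.072
2,18-29,1-3,0.045
2,18-29,>3,0.034
2,30-49,<1,0.112
2,30-49,1-3,0.08
2,30-49,>3,0.021
2,50-59,<1,0.114
2,50-59,1-3,0.034
2,50-59,>3,0.002
2,60+,<1,0.039
2,60+,1-3,0.017
2,60+,>3,0.002
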