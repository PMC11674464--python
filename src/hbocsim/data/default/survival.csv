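organ,stage,age_band,annual_excess
breast,local,<50,0.006
breast,local,50-69,0.005
breast,local,70+,0.009
breast,regional,<50,0.028
breast,regional,50-69,0.03
breast,regional,70+,0.042
breast,distant,<50,0.2
breast,distant,50-69,0.24
breast,distant,70+,0.3
ovary,local,<50,0.02
ovary,local,50-69,0.03
ovary,local,70+,0.045
ovary,regional,<50,0.09
ovary,regional,50-69,0.12
ovary,regional,70+,0.16
ovary,distant,<50,0.25
ovary,distant,50-69,0.3
ovary,distant,70+,0.38
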