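pathway,offset,cum_prob
population,40,0.007320061294
population,41,0.01524978903
population,42,0.02383996053
population,43,0.03314558223
population,44,0.04322624188
population,45,0.0541464901
population,46,0.06597625378
population,47,0.07879128379
population,48,0.09267364007
population,49,0.1077122171
population,50,0.1728766011
population,51,0.2330309092
population,52,0.2885603344
population,53,0.3398204544
population,54,0.3871395091
population,55,0.430820502
population,56,0.4711431406
population,57,0.5083656274
population,58,0.5427263134
population,59,0.5744452243
population,60,0.6037254695
population,61,0.6307545425
population,62,0.6557055215
population,63,0.6787381782
population,64,0.7
high_risk,0,0.5
high_risk,1,0.72
high_risk,2,0.84
high_risk,3,0.9
high_risk,4,0.93
high_risk,5,0.95
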