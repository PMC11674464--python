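age,prob
16,0.008274730601
17,0.01190362206
18,0.01656714042
19,0.02230792289
20,0.02906122211
21,0.03662787896
22,0.04466350736
23,0.05269107226
24,0.06014013602
25,0.06641022217
26,0.07094938216
27,0.07333401453
28,0.07333401453
29,0.07094938216
30,0.06641022217
31,0.06014013602
32,0.05269107226
33,0.04466350736
34,0.03662787896
35,0.02906122211
36,0.02230792289
37,0.01656714042
38,0.01190362206
39,0.008274730601
40,0.005565084396
41,0.003621035678
42,0.002279486428
43,0.001388303361
44,0.0008180406724
45,0.0004663463442
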