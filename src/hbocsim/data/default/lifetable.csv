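age,F,M
0,0.0035,0.0045
1,0.0002550232513,0.000615180259
2,0.0002556073453,0.0006168204571
3,0.0002562593566,0.0006186378756
4,0.0002569871825,0.0006206516627
5,0.0002577996386,0.0006228830356
6,0.0002587065655,0.0006253555042
7,0.0002597189481,0.0006280951182
8,0.0002608490487,0.0006311307424
9,0.0002621105551,0.00063449436
10,0.0002635187471,0.0006382214101
11,0.0002650906809,0.0006423511609
12,0.0002668453962,0.0006469271234
13,0.0002688041464,0.00065199751
14,0.0002709906562,0.0006576157422
15,0.0002734314092,0.0006638410138
16,0.0002761559683,0.0006707389141
17,0.0002791973338,0.0006783821194
18,0.0002825923434,0.0006868511586
19,0.0002863821182,0.0006962352614
20,0.0002906125607,0.0007066332986
21,0.0002953349109,0.0007181548241
22,0.0003006063669,0.0007309212285
23,0.0003064907776,0.0007450670186
24,0.0003130594162,0.0007607412345
25,0.0003203918435,0.0007781090197
26,0.0003285768712,0.000797353361
27,0.0003377136382,0.000818677017
28,0.0003479128108,0.0008423046534
29,0.0003592979235,0.0008684852111
30,0.0003720068751,0.0008974945284
31,0.0003861935992,0.0009296382473
32,0.0004020299281,0.000965255034
33,0.0004197076748,0.001004720147
34,0.0004394409557,0.00104844939
35,0.0004614687845,0.001096903495
36,0.0004860579668,0.001150592974
37,0.0005135063317,0.0012100835
38,0.0005441463395,0.001276001864
39,0.0005783491082,0.001349042581
40,0.000616528909,0.00142997521
41,0.0006591481833,0.001519652455
42,0.0007067231446,0.001619019157
43,0.0007598300306,0.001729122242
44,0.0008191120828,0.001851121756
45,0.0008852873376,0.001986303086
46,0.0009591573235,0.002136090502
47,0.001041616769,0.002302062164
48,0.001133664439,0.002485966749
49,0.001236415235,0.002689741876
50,0.001351113695,0.002915534517
51,0.001479149071,0.003165723625
52,0.001622072153,0.003442945191
53,0.001781614056,0.00375012002
54,0.001959707183,0.004090484507
55,0.002158508635,0.00446762473
56,0.002380426337,0.004885514239
57,0.0026281482,0.005348555915
58,0.002904674684,0.005861628365
59,0.003213355134,0.006430137318
60,0.003557928352,0.007060072585
61,0.003942567878,0.007758071162
62,0.004371932545,0.008531487159
63,0.004851222908,0.009388469286
64,0.00538624423,0.0103380467
65,0.005983476798,0.01139022416
66,0.006650154417,0.01255608739
67,0.007394352024,0.01384791993
68,0.008225083492,0.01527933253
69,0.009152410812,0.01686540653
70,0.01018756596,0.01862285282
71,0.01134308696,0.02057018785
72,0.01263296971,0.02272792872
73,0.01407283753,0.02511880941
74,0.01568013041,0.02776802021
75,0.0174743162,0.0307034732
76,0.01947712645,0.03395609632
77,0.02171281961,0.03756015919
78,0.02420847486,0.04155363421
79,0.02699432009,0.04597859662
80,0.03010409803,0.05088166782
81,0.03357547494,0.05631450655
82,0.03745049687,0.0623343532
83,0.04177609886,0.06900463284
84,0.04660467351,0.07639562353
85,0.0519947055,0.08458519673
86,0.05801148002,0.09365963776
87,0.06472787346,0.1037145549
88,0.07222523617,0.1148558868
89,0.08059437775,0.1272010184
90,0.08993666697,0.140880018
91,0.1003652596,0.1560370076
92,0.1120064688,0.1728316811
93,0.1250012953,0.1914409873
94,0.1395071352,0.2120609936
95,0.1556996862,0.2349089524
96,0.1737750758,0.2602255898
97,0.1939522367,0.2882776418
98,0.2164755591,0.3193606647
99,0.2416178499,0.3538021493
100,0.2696836377,0.3919649708
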