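age_group,children,cum_prob
15-19,0,0.9475025048
15-19,1,0.9986430011
15-19,2,0.9999785278
15-19,3,0.9999997665
15-19,4,0.9999999983
15-19,5,1
15-19,6,1
15-19,7,1
15-19,8,1
20-24,0,0.6344060988
20-24,1,0.9242253782
20-24,2,0.9900461995
20-24,3,0.9990707906
20-24,4,0.9999398475
20-24,5,0.9999976403
20-24,6,0.99999996
20-24,7,1
20-24,8,1
25-29,0,0.2683237921
25-29,1,0.6071635817
25-29,2,0.8573558232
25-29,3,0.9605598289
25-29,4,0.9916960393
25-29,5,0.9988462745
25-29,6,0.9999292866
25-29,7,1
25-29,8,1
30-34,0,0.1295194696
30-34,1,0.3191095416
30-34,2,0.6210999075
30-34,3,0.8328414102
30-34,4,0.9379838018
30-34,5,0.981927608
30-34,6,0.9975815991
30-34,7,1
30-34,8,1
35-39,0,0.1037717166
35-39,1,0.2197747114
35-39,2,0.5059040133
35-39,3,0.7503537162
35-39,4,0.8918714088
35-39,5,0.9577813565
35-39,6,0.9921685315
35-39,7,1
35-39,8,1
40-44,0,0.1002692739
40-44,1,0.2015000659
40-44,2,0.4820055845
40-44,3,0.7316021855
40-44,4,0.8809347168
40-44,5,0.9506386617
40-44,6,0.9901855949
40-44,7,1
40-44,8,1
45+,0,0.1
45+,1,0.2
45+,2,0.48
45+,3,0.73
45+,4,0.88
45+,5,0.95
45+,6,0.99
45+,7,1
45+,8,1
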