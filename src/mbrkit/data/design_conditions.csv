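condition_id,profile,feed_rate_1_per_h,S0_g_per_L,hunger_h
1,exponential,0.0875,30,0
2,exponential,0.175,30,0
3,exponential,0.35,30,0
4,constant,0.175,30,0
5,exponential,0.0875,20,0
6,exponential,0.175,20,0
7,exponential,0.35,20,0
8,constant,0.175,20,0
9,linear,0.175,30,0
10,linear,0.35,30,0
11,linear,0.175,30,2
12,linear,0.35,30,2
13,linear,0.175,20,0
14,linear,0.35,20,0
15,exponential,0.0875,20,2
16,exponential,0.35,20,2
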