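age,qx
0,0.005
1,2.9e-05
2,3.2e-05
3,3.5e-05
4,3.8e-05
5,4.2e-05
6,4.6e-05
7,5.1e-05
8,5.5e-05
9,6.1e-05
10,6.7e-05
11,7.3e-05
12,8e-05
13,8.8e-05
14,9.7e-05
15,0.000106
16,0.000117
17,0.000128
18,0.000141
19,0.000154
20,0.000169
21,0.000186
22,0.000204
23,0.000224
24,0.000246
25,0.00027
26,0.000296
27,0.000325
28,0.000357
29,0.000391
30,0.000429
31,0.000471
32,0.000517
33,0.000568
34,0.000623
35,0.000684
36,0.000751
37,0.000824
38,0.000904
39,0.000992
40,0.001089
41,0.001195
42,0.001312
43,0.001439
44,0.00158
45,0.001734
46,0.001903
47,0.002088
48,0.002292
49,0.002516
50,0.002761
51,0.00303
52,0.003325
53,0.00365
54,0.004006
55,0.004396
56,0.004825
57,0.005295
58,0.005811
59,0.006378
60,0.007
61,0.007683
62,0.008432
63,0.009254
64,0.010156
65,0.011146
66,0.012233
67,0.013426
68,0.014735
69,0.016171
70,0.017748
71,0.019479
72,0.021378
73,0.023462
74,0.02575
75,0.028261
76,0.031016
77,0.03404
78,0.03736
79,0.041002
80,0.045
81,0.049388
82,0.054203
83,0.059488
84,0.065288
85,0.071654
86,0.078641
87,0.086308
88,0.094724
89,0.103959
90,0.114096
91,0.125221
92,0.13743
93,0.15083
94,0.165536
95,0.181676
96,0.19939
97,0.218831
98,0.240168
99,0.263585
100,0.289286
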