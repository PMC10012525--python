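family,score,selected
1,1.631,0
2,3.299,1
3,2.698,1
4,1.822,0
5,1.101,0
6,0.667,0
7,1.497,0
8,2.915,1
9,2.191,0
10,2.173,0
11,2.337,0
12,1.697,0
13,1.430,0
14,2.717,1
15,2.327,0
16,2.301,0
17,2.022,0
18,1.226,0
19,2.423,0
20,2.418,0
21,1.455,0
22,1.787,0
23,2.662,1
24,1.461,0
25,2.673,1
26,1.985,0
27,2.242,0
28,1.078,0
29,1.226,0
30,1.540,0
31,3.156,1
32,1.789,0
33,2.488,0
34,1.511,0
35,1.873,0
36,1.724,0
37,1.366,0
38,0.607,0
39,2.762,1
40,2.077,0
41,2.806,1
42,1.811,0
43,1.616,0
44,1.714,0
45,1.880,0
46,0.915,0
47,0.846,0
48,2.320,0
49,1.869,0
50,1.833,0
51,2.369,0
52,1.409,0
53,1.195,0
54,2.456,0
55,1.499,0
56,2.960,1
57,1.780,0
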