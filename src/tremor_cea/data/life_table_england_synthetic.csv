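age,q_male,q_female
40,0.002084,0.001345
41,0.002292,0.001479
42,0.002521,0.001627
43,0.002773,0.00179
44,0.00305,0.001969
45,0.003354,0.002165
46,0.003689,0.002381
47,0.004057,0.002619
48,0.004462,0.002881
49,0.004907,0.003168
50,0.005397,0.003485
51,0.005935,0.003832
52,0.006526,0.004215
53,0.007176,0.004635
54,0.007891,0.005098
55,0.008677,0.005606
56,0.00954,0.006165
57,0.010489,0.006779
58,0.011532,0.007455
59,0.012678,0.008197
60,0.013937,0.009013
61,0.01532,0.00991
62,0.016839,0.010896
63,0.018507,0.011979
64,0.020339,0.013169
65,0.02235,0.014476
66,0.024557,0.015912
67,0.02698,0.017489
68,0.029637,0.019221
69,0.032552,0.021123
70,0.035749,0.023211
71,0.039253,0.025502
72,0.043092,0.028016
73,0.047298,0.030774
74,0.051903,0.033799
75,0.056943,0.037115
76,0.062455,0.04075
77,0.068482,0.044733
78,0.075067,0.049094
79,0.082257,0.053869
80,0.090101,0.059094
81,0.098651,0.064808
82,0.107965,0.071053
83,0.118098,0.077874
84,0.129112,0.08532
85,0.141069,0.093441
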