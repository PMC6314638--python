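index,x,y,Y
0,0.640,0.330,8.293
1,0.582,0.298,8.332
2,0.502,0.254,8.250
3,0.427,0.212,8.147
4,0.362,0.177,8.041
5,0.310,0.148,7.937
6,0.268,0.125,7.833
7,0.233,0.106,7.721
8,0.207,0.091,7.600
9,0.188,0.081,7.454
10,0.174,0.073,7.246
11,0.162,0.067,6.889
12,0.151,0.060,5.394
13,0.151,0.064,6.384
14,0.154,0.074,7.997
15,0.160,0.096,9.736
16,0.167,0.120,10.955
17,0.175,0.151,12.056
18,0.195,0.221,12.365
19,0.201,0.244,13.997
20,0.219,0.309,14.808
21,0.242,0.390,15.527
22,0.268,0.485,16.121
23,0.294,0.577,16.450
24,0.308,0.593,18.203
25,0.342,0.567,19.117
26,0.390,0.529,18.420
27,0.443,0.487,17.066
28,0.503,0.438,15.237
29,0.566,0.389,13.051
30,0.616,0.349,10.767
31,0.638,0.331,8.577
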