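t1_time,t1_X
0.0,0.0
5.0,36.0
10.0,66.0
15.0,84.0
20.0,91.0
25.0,100.0
30.0,100.0
35.0,89.0
40.0,99.0
45.0,95.0
50.0,83.0
55.0,90.0
60.0,93.0
65.0,86.0
70.0,92.0
75.0,99.0
80.0,99.0
85.0,95.0
90.0,87.0
95.0,104.0
100.0,89.0
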