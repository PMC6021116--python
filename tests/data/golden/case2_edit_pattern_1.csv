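t1_time,t1_StgT,t1_StringTotal,t1_N
0.0,0.0,0.0,1.95
2.5,0.026632635263186794,0.026632635263186794,1.95
5.0,0.05088975522746651,0.05088975522746651,1.95
7.5,0.07454784723140981,0.07454784723140981,1.95
10.0,0.09775752052656651,0.09775752052656651,1.95
12.5,0.12053829390031387,0.12053829390031387,1.95
15.0,0.1428989348909936,0.1428989348909936,1.95
17.5,0.16484731692170318,0.16484731692170318,1.95
20.0,0.18639105435120062,0.18639105435120062,1.95
22.5,0.20753750137375282,0.20753750137375282,1.95
25.0,0.2282941201635731,0.2282941201635731,1.95
27.5,0.24866807187597834,0.24866807187597834,1.95
30.0,0.2686663486451083,0.2686663486451083,1.95
32.5,0.2882958921959008,0.2882958921959008,1.95
35.0,0.30756355932510304,0.30756355932510304,1.95
37.5,0.32647597950969803,0.32647597950969803,1.95
40.0,0.3450397164194548,0.3450397164194548,1.95
42.5,0.36326112686720624,0.36326112686720624,1.95
45.0,0.3811466247977548,0.3811466247977548,1.95
47.5,0.39870234847540303,0.39870234847540303,1.95
50.0,0.41593440969592355,0.41593440969592355,1.95
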