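t1_time,t1_E,t1_P
0.0,1.0,0.0
0.4,0.923116346413123,0.07688365358687692
0.8,0.8521437900941226,0.14785620990587742
1.2000000000000002,0.786627861738427,0.2133721382615728
1.6,0.7261490364150883,0.27385096358491157
2.0,0.6703200439477833,0.3296799560522165
2.4000000000000004,0.6187833890699973,0.3812166109300025
2.8000000000000003,0.5712090604604374,0.42879093953956243
3.2,0.5272924202961095,0.4727075797038903
3.6,0.48675225201408145,0.5132477479859184
4.0,0.44932895801472533,0.5506710419852744
4.4,0.41478288193143625,0.5852171180685635
4.800000000000001,0.38289282531116065,0.6171071746888392
5.2,0.353454611944061,0.6465453880559388
5.6000000000000005,0.3262796804839782,0.6737203195160215
6.0,0.30119408731904224,0.6988059126809575
6.4,0.2780371691849197,0.72196283081508
6.800000000000001,0.2566606228693709,0.7433393771306289
7.2,0.2369276174138019,0.7630723825861979
7.6000000000000005,0.21871173220134524,0.7812882677986545
8.0,0.20189636169196426,0.7981036383080355
8.4,0.18637382533402885,0.8136261746659711
8.8,0.1720447016299108,0.827955298370089
9.200000000000001,0.15881727661035885,0.8411827233896411
9.600000000000001,0.14660681143846732,0.8533931885615326
10.0,0.13533513316694074,0.8646648668330591
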