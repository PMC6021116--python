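t1_time,t1_S
0.0,10.0
0.5,7.788007830534548
1.0,6.065306596629044
1.5,4.723665527311814
2.0,3.678794411747568
2.5,2.865047968507672
3.0,2.2313016013966567
3.5,8.688697210746072
4.0,6.7667641909947145
4.5,5.269961250907044
5.0,4.104249949017775
5.5,3.1963930742133453
6.0,2.4893534291483257
6.5,9.693552042372655
7.0,7.549345921146599
7.5,5.879436514871961
8.0,4.5789097619937955
8.5,3.566058508345562
9.0,2.7772491586672996
9.5,2.1629238195407186
10.0,8.42243385908564
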