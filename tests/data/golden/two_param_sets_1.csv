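t1.S:x,t1.S:y,t2.S:x,t2.S:y
0.0,10.0,0.0,10.0
0.2,9.048389871377493,0.2,7.408198550276287
0.4,8.187322737225227,0.4,5.48812460809448
0.6,7.408197269428853,0.6,4.065697803771432
0.8,6.70321108711569,0.8,3.0119532544192933
1.0,6.065315230896131,1.0,2.231309863797591
1.2,5.488123659585156,1.2,1.6529950303571326
1.4000000000000001,4.9658584463011906,1.4000000000000001,1.224568418393499
1.6,4.493288574450259,1.6,0.9071825013574419
1.8,4.065697117248066,1.8,0.6720572430447374
2.0,3.6788063056754554,2.0,0.4978720858261609
2.2,3.3287225695530687,2.2,0.3688326185133037
2.4,3.011952734338549,2.4,0.27323786369056874
2.6,2.725327536284429,2.6,0.2024195349302414
2.8000000000000003,2.4659783326988984,2.8000000000000003,0.14995604811047758
3.0,2.2313094786563394,3.0,0.1110901432252042
3.2,2.0189725374170253,3.2,0.08229758415318358
3.4,1.8268419729453216,3.4,0.06096753447899055
3.6,1.652994744458706,3.6,0.04516584954401167
3.8000000000000003,1.4956913750915903,3.8000000000000003,0.0334596765463675
4.0,1.3533573645251655,4.0,0.02478753149849655
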