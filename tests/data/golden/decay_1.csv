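t1_time,t1_S
0.0,10.0
0.1,9.512294244550219
0.2,9.048374180010011
0.3,8.607079764194578
0.4,8.187307530474362
0.5,7.788007830175126
0.6,7.4081822062364795
0.7000000000000001,7.046880896573807
0.8,6.703200459716493
0.9,6.376281515465861
1.0,6.065306596348969
1.1,5.769498103201994
1.2,5.488116360506856
1.3,5.220457767236014
1.4000000000000001,4.965853037571627
1.5,4.723665527093764
1.6,4.493289640879992
1.7,4.274149319221744
1.8,4.065696597163692
1.9000000000000001,3.8674102343412127
2.0,3.6787944115770252
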