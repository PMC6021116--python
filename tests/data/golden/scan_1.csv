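t2.S (0.1):x,t2.S (0.1):y,t2.S (0.325):x,t2.S (0.325):y,t2.S (0.55):x,t2.S (0.55):y,t2.S (0.775):x,t2.S (0.775):y,t2.S (1):x,t2.S (1):y
0.0,10.000000000000002,0.0,10.0,0.0,10.0,0.0,9.999999999999998,0.0,10.0
0.08,9.920317916085898,0.08,9.74334834315537,0.08,9.569535578502657,0.08,9.398827546545448,0.08,9.231172177065408
0.16,9.84127001475951,0.16,9.493281174328352,0.16,9.157619289973374,0.16,8.833812724044366,0.16,8.521452805845419
0.24,9.762852442263116,0.24,9.249647632469552,0.24,8.763422727024615,0.24,8.302750259542204,0.24,7.866294067653226
0.32,9.685059182276433,0.32,9.01226408485072,0.32,8.386192888237897,0.32,7.803614293733827,0.32,7.261504762961338
0.4,9.607886422267931,0.4,8.780964919659926,0.4,8.025201377100787,0.4,7.334483628967413,0.4,6.70321108711569
0.48,9.531327899205762,0.48,8.555602479930545,0.48,7.679749047348868,0.48,6.893554272868552,0.48,6.187842827022428
0.56,9.455382237766186,0.56,8.336024340489978,0.56,7.349166146047543,0.56,6.479131613158266,0.56,5.712098397606746
0.64,9.380043828510068,0.64,8.122081664508991,0.64,7.032812925645814,0.64,6.0896245119668215,0.64,5.272930928415333
0.72,9.305306958069979,0.72,7.913629583035764,0.72,6.730076127768378,0.72,5.72353350782058,0.72,4.867526899672396
0.8,9.231165944821058,0.8,7.710527630019713,0.8,6.44037217487792,0.8,5.379450883865376,0.8,4.493288574450259
0.88,9.157615107138444,0.88,7.512637736435837,0.88,6.1631393044819625,0.88,5.056053307669475,0.88,4.147828166147493
0.96,9.084648763397274,0.96,7.319826279809689,0.96,5.897840401499531,0.96,4.752094999072681,0.96,3.828936312733411
1.04,9.012261755824042,1.04,7.131963107130349,1.04,5.643961331840372,1.04,4.4664088297622415,1.04,3.534559265925698
1.12,8.940451211078646,1.12,6.9489213900550215,1.12,5.401010958546152,1.12,4.197900956530979,1.12,3.2628094459042205
1.2,8.869212851979167,1.2,6.770576592540339,1.2,5.168518490986982,1.2,3.945540401354357,1.2,3.011952734338549
1.28,8.798542158364736,1.28,6.596809269655723,1.28,4.94603325991184,1.28,3.708353662151503,1.28,2.780382804214508
1.36,8.72843461007448,1.36,6.427502684740135,1.36,4.733123545233184,1.36,3.4854197326213576,1.36,2.566616817075173
1.44,8.658885717038661,1.44,6.262541211797598,1.44,4.529378354379894,1.44,3.275886514013997,1.44,2.3692859397596746
1.52,8.589891119601143,1.52,6.10181346018021,1.52,4.334404950052043,1.52,3.0789496734912354,1.52,2.187126613359179
1.6,8.521446377760187,1.6,5.945210918515879,1.6,4.147827138228376,1.6,2.8938521068794234,1.6,2.0189725374170253
1.68,8.453547037723329,1.68,5.7926274080374744,1.68,3.969283476422266,1.68,2.719882073317719,1.68,1.8637466476604971
1.76,8.386188645698109,1.76,5.643959918357325,1.76,3.7984271839899955,1.76,2.5563706158421695,1.76,1.7204548576115684
1.84,8.319366801898855,1.84,5.499108156334459,1.84,3.634924423762412,1.84,2.402688994944737,1.84,1.5881798341397089
1.92,8.253077379373817,1.92,5.3579739456240425,1.92,3.4784547556125314,1.92,2.2582462696077754,1.92,1.4660746630537023
2.0,8.187316160905306,2.0,5.220461945876056,2.0,3.3287189871293257,2.0,2.122487027727119,2.0,1.3533573645251655
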