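t1.A:x,t1.A:y,t1.B:x,t1.B:y
0.0,10.0,0.0,0.0
0.25,8.032653236414053,0.25,1.9673467635859507
0.5,6.839397094936673,0.5,3.1606029050633317
0.75,6.115649940841249,0.75,3.8843500591587543
1.0,5.67667557023868,1.0,4.323324429761324
1.25,5.410424249828227,1.25,4.589575750171776
1.5,5.2489344969811444,1.5,4.751065503018859
1.75,5.1509862822810595,1.75,4.849013717718944
2.0,5.091577756691153,2.0,4.90842224330885
2.25,5.055544571790509,2.25,4.944455428209494
2.5,5.033689801983143,2.5,4.966310198016861
2.75,5.020434079079391,2.75,4.979565920920613
3.0,5.012393993328783,3.0,4.9876060066712204
3.25,5.007517599626771,3.25,4.992482400373232
3.5,5.00455949759374,3.5,4.995440502406264
3.75,5.002765410121029,3.75,4.997234589878975
4.0,5.001677231277646,4.0,4.998322768722358
4.25,5.001017375966861,4.25,4.998982624033142
4.5,5.00061654974857,4.5,4.999383450251433
4.75,5.00037401941592,4.75,4.999625980584083
5.0,5.0002271082268575,5.0,4.999772891773146
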