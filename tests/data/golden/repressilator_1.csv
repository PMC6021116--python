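t1.p1:x,t1.p1:y,t1.p2:x,t1.p2:y,t1.p3:x,t1.p3:y
0.0,0.0,0.0,0.0,0.0,0.0
5.0,12.405073004516879,5.0,15.876934280987255,5.0,2.2339227060398636
10.0,1.810544816502392,10.0,17.161025057810967,10.0,19.235510408103938
15.0,32.02695685393156,15.0,2.3785432375608337,15.0,9.637294432701742
20.0,3.3495765284267374,20.0,52.57365546466988,20.0,4.265617957598305
25.0,8.693172724515392,25.0,1.401574798007941,25.0,53.4996174816548
30.0,27.222377547301036,30.0,18.394640689288792,30.0,1.4164909189508088
35.0,2.5264037551691914,35.0,8.522237633127403,35.0,37.435938283670616
40.0,58.20743151931396,40.0,5.207485648376641,40.0,2.438888273326054
45.0,1.2607300406228585,45.0,46.47751601370757,45.0,11.126607675194004
50.0,23.708366716734908,50.0,1.6666543831649545,50.0,19.10467160303078
55.0,5.451411277078274,55.0,45.91539166760117,55.0,3.2163151835607575
60.0,6.759339874537476,60.0,1.7386845290569932,60.0,58.768635308484136
65.0,36.37487030954629,65.0,14.500360062259029,65.0,1.279302451226774
70.0,2.0541443705193623,70.0,12.642708078987045,70.0,30.432888139928107
75.0,53.71860580710782,75.0,4.142164697986568,75.0,3.500896666053253
80.0,1.3822156699660952,80.0,53.99578003858936,80.0,8.802377049937656
85.0,18.866787519619272,85.0,1.4310458097567635,85.0,26.515836053416628
90.0,8.127019288857905,90.0,38.37996191538379,90.0,2.5908548549618393
95.0,5.364287138709246,95.0,2.3359024167962175,95.0,58.57289431422626
100.0,45.35928858081399,100.0,11.47603432457616,100.0,1.2550338089255537
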