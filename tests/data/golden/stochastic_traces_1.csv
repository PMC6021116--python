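t2.X (0):x,t2.X (0):y,t2.X (1):x,t2.X (1):y,t2.X (2):x,t2.X (2):y
0.0,0.0,0.0,0.0,0.0,0.0
2.5,23.0,2.5,33.0,2.5,27.0
5.0,40.0,5.0,50.0,5.0,44.0
7.5,51.0,7.5,50.0,7.5,48.0
10.0,61.0,10.0,64.0,10.0,64.0
12.5,64.0,12.5,69.0,12.5,75.0
15.0,65.0,15.0,77.0,15.0,81.0
17.5,74.0,17.5,92.0,17.5,87.0
20.0,83.0,20.0,94.0,20.0,103.0
22.5,94.0,22.5,84.0,22.5,104.0
25.0,96.0,25.0,98.0,25.0,91.0
27.5,100.0,27.5,106.0,27.5,89.0
30.0,113.0,30.0,100.0,30.0,93.0
32.5,117.0,32.5,114.0,32.5,94.0
35.0,112.0,35.0,103.0,35.0,82.0
37.5,100.0,37.5,101.0,37.5,91.0
40.0,103.0,40.0,107.0,40.0,92.0
42.5,106.0,42.5,117.0,42.5,92.0
45.0,110.0,45.0,109.0,45.0,92.0
47.5,108.0,47.5,103.0,47.5,93.0
50.0,103.0,50.0,103.0,50.0,95.0
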