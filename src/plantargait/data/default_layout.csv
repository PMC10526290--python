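unit_id,sensor_id,local_index,x_mm,y_mm
0,0,0,35.0,215.0
1,0,1,45.0,215.0
2,0,2,35.0,225.0
3,0,3,45.0,225.0
4,0,4,35.0,235.0
5,0,5,45.0,235.0
6,0,6,35.0,245.0
7,0,7,45.0,245.0
8,1,0,25.0,160.0
9,1,1,35.0,160.0
10,1,2,25.0,170.0
11,1,3,35.0,170.0
12,1,4,25.0,180.0
13,1,5,35.0,180.0
14,1,6,25.0,190.0
15,1,7,35.0,190.0
16,2,0,60.0,150.0
17,2,1,70.0,150.0
18,2,2,60.0,160.0
19,2,3,70.0,160.0
20,2,4,60.0,170.0
21,2,5,70.0,170.0
22,2,6,60.0,180.0
23,2,7,70.0,180.0
24,3,0,30.0,20.0
25,3,1,40.0,20.0
26,3,2,30.0,30.0
27,3,3,40.0,30.0
28,3,4,30.0,40.0
29,3,5,40.0,40.0
30,3,6,30.0,50.0
31,3,7,40.0,50.0
32,4,0,60.0,25.0
33,4,1,70.0,25.0
34,4,2,60.0,35.0
35,4,3,70.0,35.0
36,4,4,60.0,45.0
37,4,5,70.0,45.0
38,4,6,60.0,55.0
39,4,7,70.0,55.0
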