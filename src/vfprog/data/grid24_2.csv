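location_id,x_deg,y_deg,sector
1,-9.0,21.0,2
2,-3.0,21.0,2
3,3.0,21.0,2
4,9.0,21.0,2
5,-15.0,15.0,3
6,-9.0,15.0,3
7,-3.0,15.0,2
8,3.0,15.0,2
9,9.0,15.0,1
10,15.0,15.0,1
11,-21.0,9.0,3
12,-15.0,9.0,3
13,-9.0,9.0,3
14,-3.0,9.0,2
15,3.0,9.0,2
16,9.0,9.0,1
17,15.0,9.0,1
18,21.0,9.0,1
19,-27.0,3.0,3
20,-21.0,3.0,3
21,-15.0,3.0,3
22,-9.0,3.0,3
23,-3.0,3.0,3
24,3.0,3.0,1
25,9.0,3.0,1
26,21.0,3.0,1
27,-27.0,-3.0,4
28,-21.0,-3.0,4
29,-15.0,-3.0,4
30,-9.0,-3.0,4
31,-3.0,-3.0,4
32,3.0,-3.0,6
33,9.0,-3.0,6
34,21.0,-3.0,6
35,-21.0,-9.0,4
36,-15.0,-9.0,4
37,-9.0,-9.0,4
38,-3.0,-9.0,5
39,3.0,-9.0,5
40,9.0,-9.0,6
41,15.0,-9.0,6
42,21.0,-9.0,6
43,-15.0,-15.0,4
44,-9.0,-15.0,4
45,-3.0,-15.0,5
46,3.0,-15.0,5
47,9.0,-15.0,6
48,15.0,-15.0,6
49,-9.0,-21.0,5
50,-3.0,-21.0,5
51,3.0,-21.0,5
52,9.0,-21.0,5
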