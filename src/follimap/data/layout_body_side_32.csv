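site_id,x,y,region_label
1,0.0,1.0,ring1
2,0.7071,0.7071,ring1
3,1.0,0.0,ring1
4,0.7071,-0.7071,ring1
5,0.0,-1.0,ring1
6,-0.7071,-0.7071,ring1
7,-1.0,-0.0,ring1
8,-0.7071,0.7071,ring1
9,0.0,2.0,ring2
10,1.4142,1.4142,ring2
11,2.0,0.0,ring2
12,1.4142,-1.4142,ring2
13,0.0,-2.0,ring2
14,-1.4142,-1.4142,ring2
15,-2.0,-0.0,ring2
16,-1.4142,1.4142,ring2
17,0.0,3.0,ring3
18,2.1213,2.1213,ring3
19,3.0,0.0,ring3
20,2.1213,-2.1213,ring3
21,0.0,-3.0,ring3
22,-2.1213,-2.1213,ring3
23,-3.0,-0.0,ring3
24,-2.1213,2.1213,ring3
25,0.0,4.0,ring4
26,2.8284,2.8284,ring4
27,4.0,0.0,ring4
28,2.8284,-2.8284,ring4
29,0.0,-4.0,ring4
30,-2.8284,-2.8284,ring4
31,-4.0,-0.0,ring4
32,-2.8284,2.8284,ring4
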