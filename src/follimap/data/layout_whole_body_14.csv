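site_id,x,y,region_label
1,2.0,4.5,neck-dorsal
2,3.5,4.6,scapular
3,5.0,4.7,back
4,6.5,4.6,loin-dorsal
5,8.0,4.4,rump
6,4.0,3.2,shoulder-mid
7,5.5,3.3,mid-side
8,7.0,3.2,flank-upper
9,2.5,2.8,neck-lower
10,8.5,3.0,thigh
11,4.5,2.0,lower-side
12,6.0,2.0,lower-flank
13,5.0,0.8,abdomen
14,6.8,0.7,groin
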