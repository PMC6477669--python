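specimen_no,shore0010_part_a,shore0010_part_b,shore30a_part_a,shore30a_part_b
1,45,45,5,5
2,50,40,5,5
3,60,30,5,5
4,42.5,42.5,10,5
5,50,35,10,5
6,60,25,10,5
7,40,40,10,10
8,50,30,10,10
9,60,20,10,10
10,37.5,37.5,15,10
11,45,30,15,10
12,55,20,15,10
13,32.5,32.5,20,15
14,45,20,20,15
15,50,15,20,15
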