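mix_no,OLM,AML,HCT
1,20,5,12.5
2,20,3,10
3,15,3,15
4,15,7,11.25
5,25,4,15
6,17.5,7,12.5
7,25,5,11.25
8,20,4,11.25
9,17.5,4,13.75
10,17.5,6,15
11,22.5,7,13.75
12,25,6,12.5
13,22.5,5,15
14,20,7,15
15,25,7,10
16,25,3,13.75
17,15,6,10
18,22.5,3,12.5
19,15,5,13.75
20,20,6,13.75
21,22.5,6,11.25
22,22.5,4,10
23,17.5,3,11.25
24,15,4,12.5
25,17.5,5,10
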