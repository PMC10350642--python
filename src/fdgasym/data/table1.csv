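patient,gender,age,veeg,mri,pet,mdt_ez
1,M,22,R,Negative,R/MTL,R/MTL
2,M,12,R,Negative,R/MTL,R/MTL
3,F,24,L,L/LTL/FCD,L/LTL,L/LTL
4,M,18,R,L/MTL/HS,L/MTL,L/H
5,M,38,Negative,R/MTL/HA,R/MTL,R/MTL
6,F,26,L,Negative,L/MTL,L/MTL
7,M,14,L,Negative,L/MTL,L/MTL
8,F,30,L,L/LTL/FCD,L/LTL,L/LTL
9,F,20,R,L/M-LTL/FCD,L/M-LTL,L/M-LTL
10,F,46,R,R/MTL/AS,R/MTL,R/MTL
11,M,33,L,Negative,L/MTL,L/MTL
12,M,49,R,R/T/AS,R/T,R/MTL
13,F,20,R,Negative,R/LTL,R/LTL
14,M,34,L,R/MTL/HS,R/MTL,R/MTL
15,F,22,R,Negative,R/MTL,R/MTL
16,M,17,Negative,L/LTL/FCD,L/LTL,L/LTL
17,M,30,R,R/M-LTL/FCD,R/M-LTL,R/M-LTL
18,M,25,R,R/LTL/FCD,R/LTL,R/LTL
19,M,52,L,Negative,R/MTL,R/MTL
20,F,23,R,R/MTL/AS,R/MTL,R/MTL
21,M,25,Negative,R/MTL/HA,R/MTL,R/MTL
22,M,38,R,Negative,R/LTL,R/LTL
23,M,14,L,Negative,L/LTL,L/LTL
24,M,65,R,R/MTL/AS,R/MTL,R/MTL
25,F,51,R,R/MTL/HA,R/MTL,R/MTL
26,M,24,R,Negative,R/LTL,R/LTL
27,M,34,Negative,L/LTL/AC,L/LTL,L/LTL
28,M,23,L,L/MTL/MCD,L/MTL,L/MTL
29,M,25,L,L/LTL/DNET,L/LTL,L/LTL
30,F,29,R,R/MTL/HS,R/MTL,R/MTL
31,F,12,Negative,L/MTL/HA,L/MTL,L/MTL
32,F,31,R,R/LTL/CL,R/LTL,R/LTL
33,F,32,R,R/MTL/HS,R/MTL,R/MTL
34,F,21,L,L/MTL/AS,L/MTL,L/MTL
35,F,32,L,Negative,L/MTL,L/MTL
36,F,22,R,Negative,R/MTL,R/MTL
37,M,38,L,L/LTL/FCD,L/LTL,L/LTL
38,M,54,L,Negative,L/LTL,L/LTL
39,F,25,R,R/LTL/FCD,R/LTL,R/LTL
40,F,25,L,L/LTL/FCD,L/LTL,L/LTL
41,F,55,R,Negative,R/MTL,R/MTL
42,M,22,L,L/LTL/FCD,L/LTL,L/LTL
43,M,20,L,L/LTL/FCD,L/LTL,L/LTL
44,F,16,R,Negative,R/M-LTL,R/M-LTL
45,F,29,R,R/MTL/HS,R/MTL,R/MTL
46,M,10,Negative,Negative,L/LTL,L/LTL
47,M,20,L,Negative,L/LTL,L/LTL
48,F,60,R,Negative,R/MTL,R/MTL
49,F,49,L,Negative,L/LTL,L/LTL
50,F,18,L,Negative,L/T,L/T
51,M,28,L,L/LTL/FCD,L/LTL,L/LTL
52,F,34,L,L/LTL/FCD,L/LTL,L/LTL
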