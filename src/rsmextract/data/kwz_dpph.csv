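run_id,dpph_ir,sd
1,83.90,0.35
2,78.88,0.47
3,95.73,0.36
4,83.22,0.45
5,96.60,0.35
6,78.71,0.41
7,94.35,0.36
8,92.18,0.35
9,96.63,0.35
10,97.39,0.35
11,83.68,0.51
12,97.65,0.35
13,93.41,0.38
14,90.68,0.40
15,91.15,0.35
16,86.99,0.43
17,86.36,0.40
18,83.28,0.41
19,89.24,0.36
20,94.35,0.35
21,86.52,0.50
22,84.97,0.51
23,95.50,0.35
24,93.92,0.35
25,90.21,0.39
26,86.92,0.40
27,93.65,0.39
28,92.42,0.38
29,87.20,0.45
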