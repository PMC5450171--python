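peak,rrt_precision,rrt_stability,rrt_repeatability,rpa_precision,rpa_stability,rpa_repeatability
1,0.17,0.23,0.30,0.65,1.00,1.10
2,0.18,0.17,0.14,1.24,1.11,1.24
3,0.08,0.09,0.21,1.72,1.77,1.74
4,0.03,0.03,0.03,1.15,1.85,1.35
5,0.00,0.00,0.00,0.00,0.00,0.00
6,0.08,0.12,0.11,1.55,1.55,1.65
7,0.04,0.08,0.05,0.82,0.94,0.86
8,0.05,0.08,0.06,0.87,0.72,0.57
9,0.04,0.08,0.06,0.80,0.72,0.60
10,0.04,0.06,0.05,1.08,0.92,0.71
11,0.06,0.07,0.05,0.85,1.39,1.23
12,0.06,0.05,0.04,1.37,1.49,1.63
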