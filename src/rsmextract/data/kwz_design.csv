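run_id,ethanol,temperature,ratio,time,yield,tpc,ptp1b,aglu,abts
1,50,80,20,4,35.88,45.24,79.24,77.54,69.14
2,50,80,10,3,34.02,43.07,85.49,87.71,57.76
3,50,80,20,2,38.58,47.4,67.66,77.81,68.52
4,50,60,20,2,33.8,47.33,71.93,87.45,67.17
5,30,70,20,4,35.22,43.53,80.34,98.43,67.54
6,70,80,20,3,35.75,47.05,82.62,98.17,76.91
7,50,70,20,3,39.14,47.08,87.93,94.12,75.58
8,70,70,20,2,32.88,47.36,69.25,98.10,71.22
9,30,70,30,3,37.96,46.01,72.72,93.77,66.06
10,50,70,30,2,40.74,45.89,75.41,83.32,67.78
11,50,60,30,3,33.5,48.05,81.25,94.12,55.17
12,30,70,20,2,38.71,46.96,67.13,81.41,77.12
13,50,70,20,3,39.27,48.65,87.28,98.25,77.72
14,50,80,30,3,39.13,41.76,82.16,91.69,67.75
15,70,60,20,3,33.41,47.73,73.82,78.36,55.70
16,30,70,10,3,27.88,35.99,85.25,98.71,64.39
17,70,70,30,3,35.45,41.21,74.28,98.65,82.37
18,50,70,10,2,30.88,35.84,68.02,97.72,72.73
19,70,70,20,4,34.49,44.47,71.83,88.23,77.84
20,50,70,20,3,38.03,47.99,88.05,98.02,75.03
21,30,60,20,3,34.57,48.23,78.41,98.69,65.58
22,50,60,10,3,29.83,37.74,78.82,91.81,51.10
23,50,60,20,4,36.6,45.53,66.04,93.98,55.45
24,50,70,20,3,38.88,48.04,86.05,96.89,77.13
25,50,70,10,4,30.24,40.41,83.20,94.92,57.53
26,50,70,30,4,40.35,36.95,67.15,97.40,79.90
27,30,80,20,3,36.15,45.05,87.74,75.61,52.48
28,50,70,20,3,39.37,46.70,81.27,95.87,74.11
29,70,70,10,3,29.27,41.22,79.06,97.58,59.85
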